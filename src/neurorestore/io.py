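"""File formats, study manifest handling, and the end-to-end pipeline.

On-disk conventions:

* section images — 8-bit RGB TIFF; ROI masks — 16-bit single-channel
  TIFF with a JSON legend ``{label: [region, hemisphere]}``;
* PCD pulses — 32-bit little-endian float binary, one file per
  sonication, with a JSON sidecar ``{fs_hz, n_pulses,
  samples_per_pulse, microbubbles, seed}``;
* rotation traces — CSV with header ``time_s,heading_deg``;
* tables — UTF-8 comma-separated CSV with a mandatory header row.

Every file the pipeline writes is accompanied by a provenance JSON
(tool version, parameters, SHA-256 of each input, seed), so reruns with
identical inputs are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .behavior import RotationTrace
from .pcd import PulseRecord
from .stain import SectionImage
from .synth import HistologySample

__all__ = [
    "StudyManifest",
    "ManifestError",
    "load_manifest",
    "save_manifest",
    "write_section",
    "read_section",
    "write_pulses",
    "read_pulses",
    "write_trace",
    "read_trace",
    "write_provenance",
    "run_pipeline",
]


class ManifestError(ValueError):
    """Schema violation in a study manifest."""


_PARAM_DEFAULTS: dict[str, Any] = {
    "percentile": 99.0,
    "od_max": 2.0,
    "alpha": 0.05,
    "f0": 1.5e6,
    "band": [3e6, 9e6],
    "half_width": 1.5e5,
    "cw_is_decreasing": True,
    "analysis_window": None,      # [t0, t1) seconds, e.g. [600, 3000]
    "grubbs_alpha": None,
}

_PARAM_RANGES = {
    "percentile": (50.0, 100.0),
    "od_max": (0.0, 10.0),
    "alpha": (0.0, 0.5),
}


@dataclass
class StudyManifest:
    """Validated description of a study run.

    ``groups`` maps mouse id to group name. ``simulate`` optionally holds
    a synthetic-study specification (keys ``n_sections``, ``effect``,
    ``treated_group``, ``base_fraction``, ``mouse_sd``, ``section_sd``,
    ``noise_sd``, ``shape``); when present the pipeline generates the
    histology dataset itself. ``histology`` maps mouse -> section ->
    ``{image, mask, legend}`` paths for pre-existing data.
    """

    groups: dict[str, str] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] | None = None
    histology: dict[str, dict[str, dict[str, str]]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        merged = dict(_PARAM_DEFAULTS)
        unknown = set(self.params) - set(_PARAM_DEFAULTS)
        if unknown:
            raise ManifestError(f"unknown parameter keys: {sorted(unknown)}")
        merged.update(self.params)
        for key, (lo, hi) in _PARAM_RANGES.items():
            v = merged[key]
            if not lo < v <= hi:
                raise ManifestError(f"parameter {key}={v} outside ({lo}, {hi}]")
        self.params = merged
        if self.simulate is None and not self.histology:
            raise ManifestError("manifest needs either 'simulate' or 'histology'")

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "params": self.params,
            "simulate": self.simulate,
            "histology": self.histology,
            "seed": self.seed,
        }


def load_manifest(path: str | Path) -> StudyManifest:
    """Parse and validate a YAML/JSON study manifest; unknown keys error."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ManifestError(f"manifest root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(StudyManifest)}
    unknown = set(raw) - known
    if unknown:
        raise ManifestError(f"unknown manifest keys: {sorted(unknown)}")
    return StudyManifest(**raw)


def save_manifest(manifest: StudyManifest, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest.to_dict(), sort_keys=True))


# --------------------------------------------------------------------------
# Format readers/writers
# --------------------------------------------------------------------------

def write_section(sample: HistologySample, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write a simulated section: image/mask TIFFs, legend and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{stem}_image.tif",
        "mask": out / f"{stem}_mask.tif",
        "legend": out / f"{stem}_legend.json",
        "truth": out / f"{stem}_truth.json",
    }
    img = sample.image
    if img.dtype != np.uint8:
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    tifffile.imwrite(paths["image"], img, photometric="rgb")
    tifffile.imwrite(paths["mask"], sample.mask.astype(np.uint16))
    paths["legend"].write_text(
        json.dumps({str(k): list(v) for k, v in sample.legend.items()}, indent=1)
    )
    paths["truth"].write_text(
        json.dumps(
            {
                "fractions": {f"{r}/{h}": f for (r, h), f in sample.truth_fractions.items()},
                "seed": sample.config.seed,
            },
            indent=1,
        )
    )
    return paths


def read_section(
    image_path: str | Path,
    mask_path: str | Path,
    legend_path: str | Path,
    *,
    section_id: str = "",
    mouse_id: str = "",
) -> SectionImage:
    legend_raw = json.loads(Path(legend_path).read_text())
    legend = {int(k): (v[0], v[1]) for k, v in legend_raw.items()}
    return SectionImage(
        image=tifffile.imread(image_path),
        mask=tifffile.imread(mask_path),
        legend=legend,
        section_id=section_id,
        mouse_id=mouse_id,
    )


def write_pulses(
    pulses: list[PulseRecord], signal_path: str | Path, sidecar_path: str | Path,
    *, seed: int | None = None,
) -> None:
    """Write a pulse train as float32-LE binary plus a JSON sidecar."""
    if not pulses:
        raise ValueError("no pulses to write")
    n = pulses[0].samples.size
    if any(p.samples.size != n for p in pulses):
        raise ValueError("all pulses must share a sample count")
    data = np.concatenate([p.samples for p in pulses]).astype("<f4")
    data.tofile(signal_path)
    Path(sidecar_path).write_text(
        json.dumps(
            {
                "fs_hz": pulses[0].fs,
                "n_pulses": len(pulses),
                "samples_per_pulse": n,
                "microbubbles": bool(pulses[0].microbubbles),
                "seed": seed,
            },
            indent=1,
        )
    )


def read_pulses(signal_path: str | Path, sidecar_path: str | Path) -> list[PulseRecord]:
    meta = json.loads(Path(sidecar_path).read_text())
    data = np.fromfile(signal_path, dtype="<f4").astype(float)
    n, m = int(meta["n_pulses"]), int(meta["samples_per_pulse"])
    if data.size != n * m:
        raise ValueError(
            f"signal file holds {data.size} samples, sidecar promises {n}x{m}"
        )
    return [
        PulseRecord(
            samples=data[i * m : (i + 1) * m],
            fs=float(meta["fs_hz"]),
            index=i,
            microbubbles=bool(meta["microbubbles"]),
        )
        for i in range(n)
    ]


def write_trace(trace: RotationTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "heading_deg": trace.heading_deg}).to_csv(
        path, index=False
    )


def read_trace(path: str | Path, *, mouse_id: str = "", session: str = "") -> RotationTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "heading_deg"):
        if col not in df.columns:
            raise ValueError(f"trajectory CSV missing column {col!r}")
    return RotationTrace(
        time_s=df["time_s"].to_numpy(),
        heading_deg=df["heading_deg"].to_numpy(),
        mouse_id=mouse_id,
        session=session,
    )


# --------------------------------------------------------------------------
# Provenance and pipeline
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_provenance(
    output: str | Path,
    *,
    inputs: Mapping[str, str | Path] = (),
    params: Mapping[str, Any] = (),
    seed: int | None = None,
) -> Path:
    """Write ``<output>.provenance.json`` describing how ``output`` was made."""
    out = Path(output)
    prov = {
        "tool": "neurorestore",
        "version": __version__,
        "output": out.name,
        "inputs": {name: _sha256(Path(p)) for name, p in dict(inputs).items()},
        "params": dict(params),
        "seed": seed,
    }
    path = out.with_name(out.name + ".provenance.json")
    path.write_text(json.dumps(prov, indent=1, sort_keys=True))
    return path


def run_pipeline(manifest: StudyManifest, out_dir: str | Path) -> dict[str, Path]:
    """Run simulate (optional) -> quantify -> statistics on a histology study.

    Returns the paths of the main outputs. With a ``simulate`` block the
    synthetic dataset (images, masks, legends, ground truth) is written
    under ``out_dir/data`` first and then quantified exactly like real
    data would be.
    """
    from . import stain, stats, synth

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = manifest.params
    sections: list[SectionImage] = []
    input_files: dict[str, Path] = {}

    if manifest.simulate is not None:
        sim = dict(manifest.simulate)
        n_sections = int(sim.get("n_sections", 2))
        effect = float(sim.get("effect", 1.2))
        treated = sim.get("treated_group", "IN+FUS")
        base_fraction = float(sim.get("base_fraction", 0.20))
        mouse_sd = float(sim.get("mouse_sd", 0.03))
        section_sd = float(sim.get("section_sd", 0.01))
        noise_sd = float(sim.get("noise_sd", 0.0))
        shape = tuple(sim.get("shape", (96, 96)))
        if not manifest.groups:
            raise ManifestError("simulate requires a 'groups' mapping")
        rng = np.random.default_rng(manifest.seed)
        data_dir = out / "data"
        for mouse, group in sorted(manifest.groups.items()):
            contra = max(float(rng.normal(base_fraction, mouse_sd)), 0.02)
            ipsi = contra * (effect if group == treated else 1.0)
            for s in range(n_sections):
                f_i = float(np.clip(ipsi + rng.normal(0, section_sd), 0.0, 1.0))
                f_c = float(np.clip(contra + rng.normal(0, section_sd), 0.0, 1.0))
                cfg = synth.HistologySimConfig(
                    shape=shape,
                    fractions={("striatum", "ipsi"): f_i, ("striatum", "contra"): f_c},
                    rois=synth.default_rois(shape),
                    noise_sd=noise_sd,
                    seed=int(rng.integers(2**31)),
                )
                sample = synth.gen_histology(
                    cfg, section_id=f"s{s + 1}", mouse_id=mouse
                )
                paths = write_section(sample, data_dir, f"{mouse}_s{s + 1}")
                sections.append(sample.as_section())
                input_files[f"{mouse}_s{s + 1}_image"] = paths["image"]
    else:
        for mouse, secs in sorted(manifest.histology.items()):
            for sec_id, files in sorted(secs.items()):
                for key in ("image", "mask", "legend"):
                    if key not in files:
                        raise ManifestError(
                            f"histology entry {mouse}/{sec_id} missing {key!r}"
                        )
                    if not Path(files[key]).exists():
                        raise ManifestError(
                            f"missing file for {mouse}/{sec_id}: {files[key]}"
                        )
                sections.append(
                    read_section(
                        files["image"], files["mask"], files["legend"],
                        section_id=sec_id, mouse_id=mouse,
                    )
                )
                input_files[f"{mouse}_{sec_id}_image"] = Path(files["image"])

    sec_df, mouse_df = stain.quantify_study(
        sections, percentile=params["percentile"], od_max=params["od_max"]
    )
    if manifest.groups:
        mouse_df = mouse_df.assign(
            group=[manifest.groups[m] for m in mouse_df["mouse"]]
        )

    outputs: dict[str, Path] = {}
    outputs["sections_csv"] = out / "sections.csv"
    sec_df.to_csv(outputs["sections_csv"], index=False)
    outputs["mice_csv"] = out / "mice.csv"
    mouse_df.to_csv(outputs["mice_csv"], index=False)

    if manifest.groups and mouse_df["group"].nunique() >= 2:
        results = stats.group_analysis(
            mouse_df, alpha=params["alpha"], grubbs_alpha=params["grubbs_alpha"]
        )
        outputs["results_json"] = out / "results.json"
        outputs["results_json"].write_text(
            json.dumps({r: res.to_dict() for r, res in results.items()}, indent=1)
        )
        report = []
        for region, res in results.items():
            report.append(f"== {region} ==")
            for g in sorted(res.group_means):
                report.append(
                    f"  {g}: mean ratio {res.group_means[g]:.4f} "
                    f"(SEM {res.group_sems[g]:.4f})"
                )
            a = res.anova
            report.append(f"  ANOVA: F={a.statistic:.4f}, p={a.p:.4g}")
            for (ga, gb), t in res.pairwise.items():
                report.append(
                    f"  {ga} vs {gb}: t={t.statistic:.4f}, p={t.p:.4g}, "
                    f"adj p={t.p_adjusted if t.p_adjusted is None else round(t.p_adjusted, 6)}"
                )
        outputs["report_txt"] = out / "report.txt"
        outputs["report_txt"].write_text("\n".join(report) + "\n")

    for name, path in outputs.items():
        write_provenance(
            path, inputs=input_files, params=params, seed=manifest.seed
        )
    return outputs
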