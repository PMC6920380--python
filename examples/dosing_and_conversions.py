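"""Study-design dose arithmetic and tissue-level reporting conversions.

Computes the protein mass delivered per intranasal session (droplet
volume x concentration) and over the three-session study, and converts
measured tissue concentrations to percent of the injected dose per gram
of tissue — the standard figure of merit for brain delivery efficiency.
"""

from neurorestore import stats, synth

rep = synth.session_dose(synth.BDNF_INTRANASAL_DOSE)
print(
    f"per session: {rep.droplets_per_session} droplets x "
    f"{synth.BDNF_INTRANASAL_DOSE.droplet_volume_ul} uL at "
    f"{synth.BDNF_INTRANASAL_DOSE.concentration_mg_ml} mg/mL = "
    f"{rep.volume_per_session_ul:.0f} uL -> {rep.mass_per_session_mg:.5f} mg "
    f"(~{rep.mass_per_session_mg:.1f} mg)"
)
print(f"over {synth.BDNF_INTRANASAL_DOSE.sessions} sessions: "
      f"{rep.mass_per_study_mg:.5f} mg (~{rep.mass_per_study_mg:.1f} mg)")

# delivery efficiency: measured tissue content relative to a 400 ug dose
for region, conc in (("striatum", 29.05), ("midbrain", 35.07)):
    pct = stats.pct_injected_per_gram(conc, injected_ug=400.0)
    print(f"{region}: {conc} ug/g of a 400 ug dose -> {pct} %/g")

print("ELISA normalization: 49.91 ng/mL over 1 mg/mL total protein ->",
      stats.bdnf_per_total_protein(49.91, 1.0), "ng/mg")
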