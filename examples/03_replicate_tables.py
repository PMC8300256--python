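"""Recompute the published growth-rate tables and flag inconsistencies.

The bundled county tables carry both an annual-surgeries column and a
printed growth-rate column. Recomputing r_t = ln(N_{t+1}/N_t) from the
surgeries shows that the printed rates disagree with their own counts in
several years -- a documented defect of the source data that any
re-analysis needs to surface rather than average away.
"""

from rickertnr import foley_tables

for name, frame in foley_tables().items():
    mism = frame[frame["match"] == False]  # noqa: E712
    print(f"== {name}: {len(frame)} years, "
          f"{len(mism)} printed rate(s) inconsistent with the surgeries ==")
    for _, row in mism.iterrows():
        print(f"  {row['year']}: computed {row['computed_rate']:+.2f} "
              f"vs printed {row['printed_rate']:+.2f}")
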