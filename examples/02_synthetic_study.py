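"""Generate a small synthetic delineation study and summarize it.

Eight simulated experts (tight contours, high peripheral detection)
and twelve novices (looser contours, lower peripheral detection)
delineate one whole-brain phantom; the study is summarized with the
standard descriptive tables: gross tumor volume, slices delineated,
and central/peripheral inter-observer agreement.
"""

from delinmetrics import PhantomParams, generate_study, summary_tables

phantom = PhantomParams(
    n_slices=15, width=128, height=128, brain_ellipse=(54.0, 57.0),
    tumor_center=(75, 57, 7), tumor_semi_axes=(20.0, 15.0, 4.0),
)
study = generate_study(phantoms=[phantom], n_experts=8, n_novices=12,
                       seed=2024, include_independent_set=False)
tables = summary_tables(study.dataset)

print("gross tumor volume (pixels):")
print(tables["gta_gtv"].to_string(index=False))
print("\nslices delineated:")
print(tables["slices"].to_string(index=False))
print("\ninter-observer agreement (% concordance):")
print(tables["agreement"].to_string(index=False))
# Agreement is far higher on the five central slices (sharp tumor margin)
# than on peripheral ones, and experts hold up better peripherally —
# the qualitative structure such studies report.
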