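"""qPCR quantification: reference-gene selection and 2^-ddCt fold changes.

Generates a Ct table with a configured 10.969-fold induction of cyp24a1
under treatment (plus the housekeeping panel), picks the most stable
reference gene and recovers the fold change.
"""

from osteomorph import ddct, select_reference
from osteomorph.synthetic import SimulationConfig, gen_ct

ct = gen_ct(
    {
        "cyp24a1": {"control": 1.0, "VitD3": 10.969},
        "igfbp1": {"control": 1.0, "VitD3": 5.25},
        # a second housekeeping candidate, flat across conditions
        "ef1a": {"control": 1.0, "VitD3": 1.0},
    },
    SimulationConfig(seed=42),
    replicate_sd=0.15,
    n_bio_reps=4,
)
print(f"Ct table: {len(ct)} wells "
      f"({ct['bio_rep'].max()} biological x {ct['tech_rep'].max()} technical replicates)")

reference = select_reference(ct, candidates=("gapdh", "ef1a"))
print(f"reference gene (most stable across conditions): {reference}\n")

for gene in ("cyp24a1", "igfbp1"):
    folds = ddct(ct, gene, reference, calibrator_condition="control")
    treated = folds.set_index("condition").loc["VitD3"]
    print(
        f"{gene}: fold change = {treated['fold_change']:.2f}"
        f" (replicate folds {treated['fold_mean']:.2f} +/- {treated['fold_sd']:.2f})"
    )
print(
    "\nFold changes are 2^-ddCt relative to the control calibrator; values"
    " should recover the configured 10.97 and 5.25 within replicate noise."
)
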