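"""Variable-importance stage: AIC/VIF pruning, random forest, Moran's I.

Runs the multivariate stage on the synthetic defaults and shows that the
generative driver — LGM winter coldness (LGM_MTCM) — is recovered with
normalized importance 1.0, with spatially clean residuals.
"""

import phyloldg as pl
from phyloldg.cli import importance_reports

dataset = pl.simulate_dataset(pl.SimConfig(seed=7))
summary = pl.reserve_summaries(dataset)

reports = importance_reports(summary, seed=7, responses=["mrd", "richness_Oriental"])
for resp, rep in reports.items():
    print(f"\nresponse: {resp}  (n = {rep.n}, seed = {rep.seed})")
    print("  dropped:", ", ".join(f"{nm} ({why})" for nm, why in rep.dropped) or "none")
    for pred, imp in sorted(rep.importance.items(), key=lambda kv: -kv[1]):
        marker = "  <- generative driver" if pred == "LGM_MTCM" else ""
        print(f"  importance {pred:<10} {imp:.2f}{marker}")
    sig = [m for m in rep.moran if not m.empty and m.p_value < 0.05]
    print(f"  residual Moran's I: {len(sig)}/{len(rep.moran)} distance classes "
          f"significant -> spatially independent: "
          f"{rep.residuals_spatially_independent}")
print("\nImportance 1.00 for LGM_MTCM mirrors the dominance of historical "
      "winter coldness expected under phylogenetic niche conservatism.")
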