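"""Generate a synthetic multi-batch senescence study and look at its anatomy.

The generator plants everything the analysis stages later try to recover:
five temporal modules per molecular layer, two hub metabolites whose
trajectories are shared with 30 partner genes each, per-(feature, batch)
multiplicative batch effects and pooled-QC samples.  This script generates
one study, injects the batch effects and prints what was planted.

Run:  python examples/01_synthetic_study.py
"""
import numpy as np

from senmetflux import (SyntheticConfig, generate_study, inject_batch_effects,
                        write_study)

# The default configuration is the package's reference study design:
# 4 inducer batches x 6 sampling days x 3 replicates, 60 metabolites,
# 500 genes, 5 modules per layer, 2 hubs with 30 gene partners each.
config = SyntheticConfig(seed=42)
metabolome, transcriptome, meta, truth = generate_study(config)

# The matrices come back clean; batch effects are a separate, recorded step,
# so you always know exactly what distortion was applied.
metabolome = inject_batch_effects(metabolome, truth, meta)
transcriptome = inject_batch_effects(transcriptome, truth, meta)

print(f"metabolome: {metabolome.shape[0]} features x "
      f"{metabolome.shape[1]} samples")
print(f"transcriptome: {transcriptome.shape[0]} features x "
      f"{transcriptome.shape[1]} samples")
print(f"batches: {meta.batches}")
print(f"QC samples per batch: "
      f"{ {b: len(meta.select(batch=b, role='qc')) for b in meta.batches} }")

print(f"\nplanted hub metabolites: {truth.hub_features}")
for hub, partners in truth.hub_partners.items():
    print(f"  {hub}: {len(partners)} partner genes "
          f"({partners[0]} ... {partners[-1]})")

labels = truth.metabolite_labels(metabolome.feature_ids)
for m in sorted(set(labels)):
    n = int(np.sum(labels == m))
    kind = ("unassigned noise" if m == 0
            else "hub module" if m > 10 else "metabolite module")
    print(f"module {m:>2} ({kind}): {n} metabolites")

# The injected batch effects are per-(feature, batch) multiplicative factors;
# their spread is what the correction benchmark later has to undo.
log_factors = np.log2(truth.batch_factor.to_numpy())
print(f"\nbatch factors: log2 sd = {log_factors.std():.2f} "
      f"(range {log_factors.min():.1f} .. {log_factors.max():.1f})")

paths = write_study(metabolome, transcriptome, meta, truth, "example_study")
print(f"\nwrote study to: {sorted(str(p) for p in paths.values())}")
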