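"""Cross-source Boolean query: the *04-carrier / risk-genotype cell selection.

Reproduces the classic fused-store workflow: pick cell samples whose donor
carries an HLA-DR *04 allele (shared epitope) and the rs2064476 risk
genotype AG or GG — criteria that live in the genotype table, evaluated at
sample granularity against the biobank table.
"""

from cohortfusion import (HLA_DR04_SET, And, Criterion, SynthConfig, evaluate,
                          export_results, plant_truth)

store, manifest = plant_truth(SynthConfig(ra_n=80, psoriasis_n=10, seed=12),
                              "table2_like")

expr = And(
    Criterion("genotypes", "hla_dr", "in_set", sorted(HLA_DR04_SET)),  # C1
    Criterion("genotypes", "rs2064476", "in_set", ["AG", "GG"]),        # C3
)
rs = evaluate(store, expr, granularity="sample")

cols = ["coded_id", "sample_type", "n_cells_millions", "position", "hla_dr",
        "rs2064476"]
print(rs.rows[cols].to_string(index=False))
print(f"\n{len(rs)} samples matched (fixture plants exactly "
      f"{manifest['expected_n']} among {manifest['n_decoys']} decoy patients)")
print(export_results(rs, "csv").splitlines()[0])
# Each row is one freezer specimen whose donor satisfies both genotype
# criteria; 'position' is the physical box:cell coordinate to pull.
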