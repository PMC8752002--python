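"""Offset Poisson regression of k-mer mutability, sequence vs structure.

Each genome k-mer is one observation: pooled mutation count y with
genome occurrence D as offset.  McFadden's pseudo-R^2 compares how much
of the mutation-count variation each representation explains.
"""

from pathlib import Path

from shapesig import (
    GenomeView,
    build_regression_table,
    count_opportunities,
    extract_contexts,
    fit_binning,
    fit_poisson,
    load_shape_table,
    read_mutations,
)
from shapesig.mutability import representation_k

inputs = Path("example_outputs/inputs")
genome = GenomeView(inputs / "genome.fa")
records = [r for r in read_mutations(inputs / "catalog.tsv")
           if r.sample_id == "S1"]
table = load_shape_table(inputs / "shape_table.tsv")
spec = fit_binning(table)

print(f"sample S1: {len(records)} mutations")
for rep in ("3nt-seq", "5nt-seq", "5nt-str"):
    k = representation_k(rep)
    ctxs, _ = extract_contexts(genome, records, k)
    opp = count_opportunities(genome, k)
    shape = (table, spec) if rep.endswith("str") else None
    reg = build_regression_table(ctxs, opp, rep, shape)
    fit = fit_poisson(reg)
    print(f"  {rep}: {len(reg)} k-mer rows, pseudo-R2 = {fit.pseudo_r2:.3f}")

# A coefficient above 0 means that feature level raises the mutation rate
# of a k-mer relative to the reference level (A flanks / C center / M bin),
# after adjusting for how often the k-mer occurs in the genome.
ctxs, _ = extract_contexts(genome, records, 3)
fit3 = fit_poisson(build_regression_table(ctxs, count_opportunities(genome, 3),
                                          "3nt-seq"))
top = fit3.coefficients.dropna().sort_values("estimate", ascending=False)
row = top.iloc[0]
print(f"strongest enrichment: {row['feature']}[{row['level']}] "
      f"beta = {row['estimate']:.2f} "
      f"(95% CI {row['ci_lo']:.2f}..{row['ci_hi']:.2f})")
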