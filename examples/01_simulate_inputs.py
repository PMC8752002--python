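"""Generate a complete synthetic study: genome, shape table, catalog.

Everything downstream (spectra, regression, PCA, NMF) runs on these
files; re-running with the same seeds reproduces them byte for byte.
"""

from pathlib import Path

from shapesig import simulate as sim
from shapesig import write_shape_table
from shapesig.signatures import SignatureCatalog

out = Path("example_outputs/inputs")
out.mkdir(parents=True, exist_ok=True)

genome = sim.make_genome(100_000, gc=0.41, seed=1, path=out / "genome.fa")
table = sim.make_shape_table(seed=2, honor_forbidden=True)
write_shape_table(table, out / "shape_table.tsv")

signatures = sim.make_signatures(4, seed=3)
SignatureCatalog(profiles=signatures).to_tsv(out / "signatures.tsv")
exposures = sim.make_exposures(n_samples=30, n_signatures=4, seed=4)
records = sim.simulate_catalog(genome, signatures, exposures,
                               n_mut=3000, seed=5)
sim.write_catalog_tsv(records, out / "catalog.tsv")

gc = sum(b in "GC" for b in genome["chr1"]) / len(genome["chr1"])
print(f"genome: {len(genome['chr1']):,} bp, GC {gc:.3f}")
print(f"shape table: {len(table.index)} pentamers x 19 descriptors")
print(f"catalog: {len(records):,} mutations across 30 samples, "
      f"drawn from 4 ground-truth signatures")
# The catalog is a mixture: each sample draws its mutations from the four
# signatures in Dirichlet(1) proportions, placed at genome positions that
# carry the drawn trinucleotide context.
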