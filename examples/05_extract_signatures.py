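"""Bootstrap-NMF signature extraction with catalog matching.

Factorizes the dual-block spectrum matrix over many multinomial
bootstraps and component numbers, matches pooled candidates against the
reference catalog on their trinucleotide halves, and searches the
remaining candidates for novel structural signatures.
"""

from pathlib import Path

from shapesig import (
    SignatureCatalog,
    discover_novel,
    hierarchical_extract,
    read_spectra,
    select_known,
)
from shapesig.signatures import write_signatures

matrix = read_spectra(Path("example_outputs/spectra.tsv"))
catalog = SignatureCatalog.from_tsv(
    Path("example_outputs/inputs/signatures.tsv")
)

# scaled-down run: 20 bootstraps, k = 2..5 (production defaults are 300
# bootstraps and 10000 iterations)
pool = hierarchical_extract(matrix, range(2, 6), n_boot=20, seed=7,
                            max_iter=2000, tol=1e-7)
print(f"pooled {len(pool)} NMF runs "
      f"(rounds seen: {sorted({r.round for r in pool})})")

known = select_known(pool, catalog)
for sig in known:
    name, cos = sig.primary_match
    print(f"  recovered {sig.name}: best match {name} at cosine {cos:.3f}, "
          f"total exposure {sig.total_exposure:.0f}")

novel = discover_novel(pool, catalog, cluster_k_range=range(2, 9), seed=8)
print(f"novel signatures (catalog cosine < 0.8): "
      f"{[s.name for s in novel] or 'none'}")
# All four generating signatures sit in the catalog, so any SBS-SS
# reported here is a candidate to inspect, not a confirmed novel process:
# factorizations at too-small k produce mixture components that resemble
# no single catalog entry.  Withholding one generating signature from
# signatures.tsv makes a genuine SBS-SS appear that matches it closely.

write_signatures(known + novel, Path("example_outputs/signatures"))
print("wrote profiles and exposures to example_outputs/signatures/")
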