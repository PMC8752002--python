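"""Reference simulation studies exercising the whole framework.

These are the package's own calibration/recovery experiments, run at
desk scale on synthetic genomes and catalogs: Wald confidence-interval
coverage of the Poisson mutability model, block attribution of a planted
structural signal in PCA, and end-to-end recovery of planted known and
novel signatures through the bootstrap-NMF pipeline.  Each study takes a
single seed and derives all internal randomness from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import simulate as sim
from .contexts import count_opportunities
from .mutability import build_regression_table, design_matrix, fit_poisson
from .pca import dual_block_contributions, run_pca
from .shape import fit_binning
from .signatures import (
    SignatureCatalog,
    cosine_similarity,
    discover_novel,
    hierarchical_extract,
    select_known,
)
from .spectra import build_sample_spectra, spectra_to_frame


def _subseeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def wald_coverage_study(
    seed: int,
    *,
    n_rep: int = 200,
    genome_length: int = 100_000,
    beta: dict[str, float] | None = None,
    mean_rate: float = 0.05,
) -> dict:
    """Coverage of 95% Wald CIs for Poisson coefficients on pentamer tables.

    A fixed random genome provides the 512 pentamer opportunity rows;
    counts are simulated ``n_rep`` times from known coefficients and the
    fraction of replicates whose CI covers the truth is averaged over the
    non-reference coefficients.
    """
    seeds = _subseeds(seed, n_rep + 1)
    genome = sim.make_genome(genome_length, gc=0.45, seed=seeds[0])
    opp = count_opportunities(genome, 5)
    table = build_regression_table([], opp, "5nt-seq")
    if beta is None:
        beta = {"center[T]": 0.6, "pos+1[G]": -0.4, "pos-2[C]": 0.3}
    X, _ = design_matrix(table)
    full = dict(beta, intercept=np.log(mean_rate))
    covered = {name: 0 for name in beta}
    for r in range(n_rep):
        t = table.copy()
        t["y"] = sim.simulate_poisson_counts(t, full, seed=seeds[r + 1])
        fit = fit_poisson(t)
        coefs = fit.coefficients.set_index(
            fit.coefficients["feature"] + "[" + fit.coefficients["level"] + "]"
        )
        for name, true_val in beta.items():
            row = coefs.loc[name]
            if row["ci_lo"] <= true_val <= row["ci_hi"]:
                covered[name] += 1
    per_coef = {k: v / n_rep for k, v in covered.items()}
    return {
        "coverage": float(np.mean(list(per_coef.values()))),
        "per_coefficient": per_coef,
        "n_rep": n_rep,
        "n_rows": len(table),
    }


def pc1_block_study(
    seed: int,
    *,
    n_rep: int = 100,
    n_samples: int = 25,
    signal_sd: float = 3.0,
) -> dict:
    """How often a structural-only planted signal dominates PC1.

    Each replicate plants a rank-one signal in the structural half of a
    noise matrix; success means the structural block contributes more of
    PC1's variance than the sequence block.
    """
    wins = 0
    for s in _subseeds(seed, n_rep):
        rng = np.random.default_rng(s)
        M = rng.normal(0.0, 1.0, size=(n_samples, 192))
        pattern = rng.random(96)
        M[:, 96:] += np.outer(rng.normal(0.0, signal_sd, size=n_samples),
                              pattern)
        contrib = dual_block_contributions(run_pca(M))
        if contrib["struct"].iloc[0] > contrib["seq"].iloc[0]:
            wins += 1
    return {"win_rate": wins / n_rep, "n_rep": n_rep}


@dataclass
class RecoveryResult:
    """Outcome of one planted-signature end-to-end run."""

    known_cosines: dict[str, float]
    n_known_recovered: int
    novel_cosine: float
    novel_recovered: bool
    n_selected: int
    n_novel: int
    pool_size: int


def planted_signature_study(
    seed: int,
    *,
    n_known: int = 4,
    n_samples: int = 60,
    n_mut: int = 5000,
    n_boot: int = 30,
    k_range=range(2, 7),
    genome_length: int = 100_000,
    max_iter: int = 2000,
    tol: float = 1e-7,
    cluster_k_range=range(2, 11),
    recovery_cos: float = 0.95,
) -> RecoveryResult:
    """End-to-end recovery of planted known and novel signatures.

    Ground truth is ``n_known`` + 1 mutually dissimilar trinucleotide
    profiles; catalogs are sampled from Dirichlet(1) mixtures of all of
    them, but the reference catalog sees only the known profiles (plus two
    decoys never used in simulation).  Success requires each known profile
    to be selected at trinucleotide cosine >= ``recovery_cos`` and a
    discovered novel signature at the same cosine to the held-out profile.
    """
    seeds = _subseeds(seed, 8)
    genome = sim.make_genome(genome_length, gc=0.45, seed=seeds[0])
    table = sim.make_shape_table(seed=seeds[1], honor_forbidden=True)
    spec = fit_binning(table)
    truth = sim.make_signatures(n_known + 3, seed=seeds[2])
    known = truth.iloc[:, :n_known]
    novel = truth.iloc[:, n_known].to_numpy()
    decoys = truth.iloc[:, n_known + 1:]
    catalog = SignatureCatalog(profiles=pd.concat(
        [known.add_prefix("KNOWN_"), decoys.add_prefix("DECOY_")], axis=1
    ))
    used = pd.concat([known, truth.iloc[:, [n_known]]], axis=1)
    exposures = sim.make_exposures(n_samples, n_known + 1, seed=seeds[3])
    records = sim.simulate_catalog(genome, used, exposures, n_mut,
                                   seed=seeds[4])
    spectra = build_sample_spectra(genome, records, table, spec,
                                   seed=seeds[5])
    matrix = spectra_to_frame(spectra)
    pool = hierarchical_extract(matrix, k_range, n_boot=n_boot,
                                seed=seeds[6], max_iter=max_iter, tol=tol)
    selected = select_known(pool, catalog)
    known_cos: dict[str, float] = {}
    for name in known.columns:
        target = known[name].to_numpy()
        best = 0.0
        for s in selected:
            best = max(best, cosine_similarity(s.trinucleotide_half, target))
        known_cos[name] = best
    novel_found = discover_novel(pool, catalog, seed=seeds[7],
                                 cluster_k_range=cluster_k_range)
    novel_cos = max(
        (cosine_similarity(s.trinucleotide_half, novel) for s in novel_found),
        default=0.0,
    )
    return RecoveryResult(
        known_cosines=known_cos,
        n_known_recovered=sum(c >= recovery_cos for c in known_cos.values()),
        novel_cosine=float(novel_cos),
        novel_recovered=novel_cos >= recovery_cos,
        n_selected=len(selected),
        n_novel=len(novel_found),
        pool_size=len(pool),
    )
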