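"""NMF extraction, catalog matching, naming and novel-signature discovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shapesig import (
    SignatureCatalog,
    bootstrap_spectrum,
    cosine_similarity,
    discover_novel,
    hierarchical_extract,
    name_signature,
    nmf_multiplicative,
    select_known,
    seq_feature_labels,
)
from shapesig.signatures import NMFRun, reconstruction_cosines


# ---------------------------------------------------------------------------
# cosine


@pytest.mark.parametrize(
    "u, v, expected",
    [
        ((1, 2, 3), (1, 2, 3), 1.0),
        ((1, 0, 0), (0, 1, 1), 0.0),
        ((1, 1, 0), (1, 0, 1), 0.5),
    ],
)
def test_cosine_examples(u, v, expected):
    assert cosine_similarity(np.array(u), np.array(v)) == pytest.approx(expected)


def test_cosine_rejects_zero_vector():
    with pytest.raises(ValueError):
        cosine_similarity(np.zeros(3), np.ones(3))


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_preserves_row_sums(rng):
    M = rng.integers(0, 40, size=(8, 192))
    B = bootstrap_spectrum(M, seed=3)
    assert (B.sum(axis=1) == M.sum(axis=1)).all()
    assert (bootstrap_spectrum(M, seed=3) == B).all()
    assert not (bootstrap_spectrum(M, seed=4) == B).all()


def test_bootstrap_zero_row_passthrough():
    M = np.zeros((2, 10), dtype=int)
    M[1, 3] = 7
    B = bootstrap_spectrum(M, seed=0)
    assert (B[0] == 0).all() and B[1].sum() == 7


def test_bootstrap_cell_expectation(rng):
    """Per-cell mean over replicates approaches the original within 3 SE."""
    row = np.array([[500, 300, 150, 50]])
    n_rep = 1000
    total = np.zeros(4)
    rng = np.random.default_rng(11)
    for _ in range(n_rep):
        total += bootstrap_spectrum(row, rng)[0]
    mean = total / n_rep
    n = row.sum()
    p = row[0] / n
    se = np.sqrt(n * p * (1 - p) / n_rep)
    assert (np.abs(mean - row[0]) <= 3 * se).all()


# ---------------------------------------------------------------------------
# NMF


def test_nmf_objective_monotone_and_nonnegative(rng):
    V = rng.poisson(15.0, size=(30, 12)).astype(float)
    run = nmf_multiplicative(V, 3, seed=5, max_iter=400, track_objective=True)
    trace = run.objective_trace
    assert (np.diff(trace) <= 1e-9 * trace[0] + 1e-9).all()
    assert (run.W >= 0).all() and (run.H >= 0).all()
    # W columns are L1-normalized with scale absorbed into H
    assert np.allclose(run.W.sum(axis=0), 1.0)


def test_nmf_recovers_planted_factorization(rng):
    W0 = rng.random((40, 3))
    H0 = rng.random((3, 20)) * 50
    V = W0 @ H0
    run = nmf_multiplicative(V, 3, seed=9, max_iter=5000, tol=1e-12)
    rel_err = np.linalg.norm(V - run.W @ run.H) / np.linalg.norm(V)
    assert rel_err < 1e-3


def test_nmf_comparable_to_sklearn(rng):
    """Final objective is in the same range as sklearn's MU solver."""
    from sklearn.decomposition import NMF

    V = rng.poisson(10.0, size=(50, 20)).astype(float)
    ours = nmf_multiplicative(V, 4, seed=2, max_iter=3000, tol=1e-10)
    ref = NMF(n_components=4, solver="mu", init="random", random_state=2,
              max_iter=3000, tol=1e-10).fit(V)
    ref_obj = ref.reconstruction_err_ ** 2
    assert ours.objective <= 1.1 * ref_obj


def test_nmf_input_validation(rng):
    V = rng.random((10, 5))
    with pytest.raises(ValueError):
        nmf_multiplicative(V, 0)
    with pytest.raises(ValueError):
        nmf_multiplicative(V, 5)
    with pytest.raises(ValueError):
        nmf_multiplicative(-V, 2)


# ---------------------------------------------------------------------------
# hierarchical extraction


def test_hierarchical_pool_bookkeeping(rng):
    M = rng.poisson(25.0, size=(10, 192))
    pool = hierarchical_extract(M, [2, 3], n_boot=2, recon_cos=1.0,
                                max_rounds=3, seed=1, max_iter=50, tol=1e-4)
    # unattainable threshold: no removal, 3 full rounds
    assert len(pool) == 2 * 2 * 3
    assert {run.round for run in pool} == {1, 2, 3}
    assert all(len(run.sample_ids) == 10 for run in pool)


def test_hierarchical_removal_shrinks_rounds(rng):
    M = rng.poisson(60.0, size=(12, 192))
    pool = hierarchical_extract(M, [2, 3], n_boot=3, recon_cos=0.5,
                                max_rounds=3, seed=1, max_iter=100, tol=1e-6)
    # everything reconstructs above cosine 0.5: one round only
    assert {run.round for run in pool} == {1}


def test_hierarchical_requires_enough_samples(rng):
    with pytest.raises(ValueError, match="samples"):
        hierarchical_extract(rng.poisson(5.0, size=(3, 192)), [4], n_boot=1)


def test_removed_samples_were_well_reconstructed(rng):
    """Samples absent from round 2 exceeded the removal threshold in round 1."""
    M = rng.poisson(40.0, size=(10, 192))
    thresh = 0.9
    pool = hierarchical_extract(M, [3], n_boot=3, recon_cos=thresh,
                                max_rounds=2, seed=7, max_iter=300, tol=1e-8)
    round1 = [r for r in pool if r.round == 1]
    round2 = [r for r in pool if r.round == 2]
    if round2:
        removed = set(round1[0].sample_ids) - set(round2[0].sample_ids)
        V = M.T.astype(float)
        ids = round1[0].sample_ids
        best = np.zeros(len(ids))
        for run in round1:
            best = np.maximum(best, reconstruction_cosines(run, V))
        for sid in removed:
            assert best[ids.index(sid)] > thresh


# ---------------------------------------------------------------------------
# naming


@pytest.mark.parametrize(
    "sims, expected",
    [
        ({"SBS15": 0.96, "SBS6": 0.88}, "SBS15/6L"),
        ({"SBS4": 0.90}, "SBS4L"),
        ({"SBS7a": 0.99}, "SBS7a"),
        ({"SBS1": 0.86, "SBS5": 0.97, "SBS40": 0.91}, "SBS5/40L/1L"),
    ],
)
def test_name_signature_examples(sims, expected):
    assert name_signature(sims) == expected


def test_name_signature_requires_match():
    with pytest.raises(ValueError):
        name_signature({"SBS1": 0.80})


@settings(max_examples=200, derandomize=True)
@given(
    sims=st.dictionaries(
        st.sampled_from([f"SBS{i}" for i in range(1, 30)]),
        st.floats(min_value=0.0, max_value=1.0),
        min_size=1,
        max_size=8,
    )
)
def test_name_signature_properties(sims):
    """Naming is a pure threshold/ordering function of the similarity map."""
    hits = {n: c for n, c in sims.items() if c >= 0.85}
    if not hits:
        with pytest.raises(ValueError):
            name_signature(sims)
        return
    name = name_signature(sims)
    # independent reconstruction of the stated rule: matches sorted by
    # decreasing cosine (ties alphabetical), SBS prefix elided after the
    # primary, L suffix below cosine 0.95
    ordered = sorted(hits.items(), key=lambda nc: (-nc[1], nc[0]))
    expected = "/".join(
        (cat if i == 0 else cat[3:]) + ("L" if cos < 0.95 else "")
        for i, (cat, cos) in enumerate(ordered)
    )
    assert name == expected


# ---------------------------------------------------------------------------
# selection and novelty on a controlled pool


def _pool_from_profiles(profiles, n_samples=5, k_tag=3):
    """Wrap fixed 192-profiles as a single synthetic NMF run."""
    W = np.stack(profiles, axis=1)
    W = W / W.sum(axis=0)
    H = np.abs(np.random.default_rng(0).random((W.shape[1], n_samples))) * 100
    return [NMFRun(W=W, H=H, k=W.shape[1], bootstrap=0, round=1,
                   sample_ids=[f"s{i}" for i in range(n_samples)],
                   objective=0.0, converged=True, n_iter=1)]


def _catalog(profiles_96, names):
    df = pd.DataFrame(np.column_stack(profiles_96),
                      index=seq_feature_labels(), columns=names)
    return SignatureCatalog(profiles=df)


def test_select_known_threshold_and_structural_blindness(rng):
    cat_a = rng.random(96) ** 3
    cat_b = rng.random(96) ** 3
    catalog = _catalog([cat_a, cat_b], ["SBS_A", "SBS_B"])
    # candidate 1 matches A exactly; candidate 2 matches nothing
    noise = rng.random(96) ** 6
    prof1 = np.concatenate([cat_a, rng.random(96)])
    prof2 = np.concatenate([noise, rng.random(96)])
    pool = _pool_from_profiles([prof1, prof2])
    selected = select_known(pool, catalog)
    assert [s.primary_match[0] for s in selected] == ["SBS_A"]
    assert selected[0].primary_match[1] > 0.999
    # perturbing the structural half leaves matching unchanged
    pool2 = _pool_from_profiles(
        [np.concatenate([cat_a, rng.random(96)]), prof2]
    )
    selected2 = select_known(pool2, catalog)
    assert [s.primary_match[0] for s in selected2] == ["SBS_A"]
    assert selected2[0].primary_match[1] == pytest.approx(
        selected[0].primary_match[1]
    )


def test_select_known_exposures_come_from_run(rng):
    cat = rng.random(96) ** 3
    catalog = _catalog([cat], ["SBS_X"])
    pool = _pool_from_profiles([np.concatenate([cat, rng.random(96)])])
    (sig,) = select_known(pool, catalog)
    assert sig.exposures == dict(zip(pool[0].sample_ids, pool[0].H[0]))


def test_discover_novel_planted_orthogonal_profile(rng):
    """A pooled profile orthogonal to the catalog surfaces as an SBS-SS."""
    cat_profiles = [rng.random(96) ** 3 for _ in range(3)]
    catalog = _catalog(cat_profiles, ["SBS_A", "SBS_B", "SBS_C"])
    novel96 = np.zeros(96)
    novel96[rng.choice(96, 5, replace=False)] = 1.0
    profiles = []
    for c in cat_profiles:
        for _ in range(6):  # clusters of near-catalog candidates
            profiles.append(np.concatenate([c + rng.normal(0, 0.01, 96).clip(-c * 0.5),
                                            rng.random(96)]))
    for _ in range(6):
        profiles.append(np.concatenate([novel96 + rng.uniform(0, 0.02, 96),
                                        rng.random(96)]))
    profiles = [np.abs(p) for p in profiles]
    pool = _pool_from_profiles(profiles)
    found = discover_novel(pool, catalog, cluster_k_range=range(2, 8), seed=5)
    assert found, "no novel signature discovered"
    best = max(
        cosine_similarity(s.profile[:96], novel96) for s in found
    )
    assert best > 0.95
    assert all(s.name.startswith("SBS-SS") for s in found)
    # determinism under fixed seeds
    again = discover_novel(pool, catalog, cluster_k_range=range(2, 8), seed=5)
    assert [s.name for s in again] == [s.name for s in found]
    assert all(
        np.allclose(a.profile, b.profile) for a, b in zip(found, again)
    )


def test_discover_novel_borderline_medoid_excluded(rng):
    """A medoid at catalog cosine 0.82 is not novel (threshold is < 0.8)."""
    # catalog profile and a disjoint-support direction: their cosine is 0,
    # so a t / sqrt(1-t^2) mixture has catalog cosine exactly t = 0.82
    cat = np.zeros(96)
    cat[:48] = rng.random(48) + 0.1
    catalog = _catalog([cat], ["SBS_A"])
    orth = np.zeros(96)
    orth[48:] = rng.random(48) + 0.1
    target = 0.82
    mix = target * cat / np.linalg.norm(cat) + \
        np.sqrt(1 - target ** 2) * orth / np.linalg.norm(orth)
    cos = cosine_similarity(mix, cat)
    assert 0.80 <= cos < 0.85
    profiles = [np.concatenate([mix, rng.random(96)]) for _ in range(8)]
    pool = _pool_from_profiles(profiles)
    found = discover_novel(pool, catalog, cluster_k_range=range(2, 5), seed=1)
    assert found == []
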