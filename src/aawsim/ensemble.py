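"""Ensemble experiments on simulated antibody repertoires.

Two experiment drivers reproduce the simulator's headline behaviour:

* :func:`diversity_sweep` — how predictive performance (Q^2), pairwise
  agreement of estimated amino-acid weights and recovery of the generative
  weights h improve as the antibody mixture grows more diverse (from a
  single monoclonal antibody to tens of thousands of variants);
* :func:`dominance_experiment` — how multiplicative measurement noise and a
  single dominant antibody (10-fold or 1000-fold concentration excess over a
  uniform background of 15999 variants, as in an acute immune response)
  degrade both statistics.

Supporting statistics: pairwise Pearson correlation of weight vectors,
correlation with the generative h, PCA of weight-vector collections, rank
correlation with published per-amino-acid property scales, and the
two-sided Wilcoxon rank-sum test for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .binding import ThermoParams, make_mixture, sample_antibody, simulate_profile
from .library import ALPHABET, PeptideLibrary, composition_matrix
from .regression import fit_aaws, q2_cross_validation

#: The four noise/dominance scenarios: (sigma, dominance factor) at
#: n_ab = 16000.  Case I is the clean baseline; II adds multiplicative
#: noise; III and IV add a 10-fold and 1000-fold dominant antibody.
DOMINANCE_CASES: dict[str, tuple[float, float]] = {
    "I": (0.0, 1.0),
    "II": (0.01, 1.0),
    "III": (0.01, 10.0),
    "IV": (0.01, 1000.0),
}


@dataclass(frozen=True)
class SweepResult:
    """Replicate statistics per antibody-diversity grid point."""

    n_ab_grid: list[int]
    q2_samples: list[list[float]]
    pairwise_r_samples: list[list[float]]
    h_recovery_samples: list[list[float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, n_ab in enumerate(self.n_ab_grid):
            for rep, (q2, r) in enumerate(
                zip(self.q2_samples[i], self.h_recovery_samples[i])
            ):
                rows.append({"n_ab": n_ab, "replicate": rep, "q2": q2, "h_recovery": r})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DominanceResult:
    """Replicate statistics for one noise/dominance case."""

    case: str
    sigma: float
    dominance_factor: float
    q2_samples: list[float]
    pairwise_r_samples: list[float]


@dataclass(frozen=True)
class PcaResult:
    """PCA of a collection of weight vectors: sample scores, per-component
    variance-explained fractions and the 20-row loadings."""

    scores: np.ndarray
    variance_explained: np.ndarray
    loadings: np.ndarray


def pairwise_aaws_correlation(W: np.ndarray | Sequence) -> np.ndarray:
    """Pearson r for every unordered pair of weight vectors.

    ``W`` is (m, 20) (rows may also be :class:`~aawsim.regression.AAWSEstimate`
    objects); m estimates give m(m-1)/2 values (upper triangle, no diagonal).
    """
    rows = [w.w if hasattr(w, "w") else np.asarray(w, dtype=float) for w in W]
    W = np.vstack(rows)
    if W.shape[0] < 2:
        raise ValueError("need at least two weight vectors")
    if np.any(W.std(axis=1) == 0):
        raise ValueError("constant weight vector: correlation undefined")
    C = np.corrcoef(W)
    iu = np.triu_indices(W.shape[0], k=1)
    return C[iu]


def h_recovery(w, h: np.ndarray) -> float:
    """Pearson correlation between an estimated weight vector and the
    generative weights h — the parameter-identifiability check."""
    w = w.w if hasattr(w, "w") else np.asarray(w, dtype=float)
    h = np.asarray(h, dtype=float)
    if w.shape != (20,) or h.shape != (20,):
        raise ValueError("w and h must be 20-vectors")
    if w.std() == 0 or h.std() == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    return float(stats.pearsonr(w, h)[0])


def _one_run(
    lib: PeptideLibrary,
    X: np.ndarray,
    h: np.ndarray,
    n_ab: int,
    theta: ThermoParams,
    rng: np.random.Generator,
    sigma: float = 0.0,
    dominance_factor: float = 1.0,
    dominant: np.ndarray | None = None,
    folds: int = 10,
    n_components: int | None = None,
):
    """One replicate: fresh mixture -> simulate -> normalize -> fit -> score."""
    mix = make_mixture(
        n_ab, lib.length, rng, dominance_factor=dominance_factor, dominant=dominant
    )
    s = simulate_profile(lib, mix, h, theta, sigma=sigma, noise_seed=rng)
    cv_seed = int(rng.integers(2**31))
    cv = q2_cross_validation(s, X, folds=folds, seed=cv_seed, n_components=n_components)
    est = fit_aaws(s, X, n_components=n_components, seed=cv_seed)
    return cv.q2, est


def diversity_sweep(
    n_ab_grid: Sequence[int],
    reps: int = 100,
    lib: PeptideLibrary | None = None,
    h: np.ndarray | None = None,
    theta: ThermoParams = ThermoParams(),
    seed: int = 0,
    n_components: int | None = None,
    regenerate_library: bool = False,
) -> SweepResult:
    """Sweep antibody diversity: for each grid value of n_ab run ``reps``
    replicates, each with a newly generated random mixture, and record Q^2,
    pairwise weight-vector correlation and h-recovery.

    The peptide library and the generative weights h are generated once and
    held fixed across all runs (pass ``regenerate_library=True`` to redraw
    the library per replicate instead; the distributions are insensitive to
    this choice).
    """
    if not n_ab_grid:
        raise ValueError("empty n_ab grid")
    from .library import generate_library  # local import avoids cycle at module load

    root = np.random.SeedSequence(seed)
    lib_ss, h_ss, run_ss = root.spawn(3)
    if lib is None:
        lib = generate_library(255, 14, np.random.default_rng(lib_ss))
    if h is None:
        from .binding import sample_assigned_aaws

        h = sample_assigned_aaws(np.random.default_rng(h_ss))
    X = composition_matrix(lib)
    rng = np.random.default_rng(run_ss)

    q2_all, pr_all, hr_all = [], [], []
    for n_ab in n_ab_grid:
        q2s, hrs, ests = [], [], []
        for _ in range(reps):
            if regenerate_library:
                lib = generate_library(255, 14, rng)
                X = composition_matrix(lib)
            q2, est = _one_run(lib, X, h, n_ab, theta, rng, n_components=n_components)
            q2s.append(q2)
            hrs.append(h_recovery(est, h))
            ests.append(est)
        q2_all.append(q2s)
        hr_all.append(hrs)
        pr_all.append(list(pairwise_aaws_correlation(ests)) if reps > 1 else [])
    return SweepResult(
        n_ab_grid=list(n_ab_grid),
        q2_samples=q2_all,
        pairwise_r_samples=pr_all,
        h_recovery_samples=hr_all,
    )


def dominance_experiment(
    reps: int = 100,
    lib: PeptideLibrary | None = None,
    h: np.ndarray | None = None,
    theta: ThermoParams = ThermoParams(),
    seed: int = 0,
    n_ab: int = 16000,
    n_components: int | None = None,
    cases: Sequence[str] = ("I", "II", "III", "IV"),
) -> list[DominanceResult]:
    """Run the four noise/dominance cases on a fixed library and h.

    A single dominant antibody is generated once and shared across all
    cases; every replicate draws a fresh background mixture of n_ab - 1
    antibodies to which the dominant one is added (at 1x, 10x or 1000x
    weight depending on the case).
    """
    from .binding import sample_assigned_aaws
    from .library import generate_library

    root = np.random.SeedSequence(seed)
    lib_ss, h_ss, dom_ss, run_ss = root.spawn(4)
    if lib is None:
        lib = generate_library(255, 14, np.random.default_rng(lib_ss))
    if h is None:
        h = sample_assigned_aaws(np.random.default_rng(h_ss))
    X = composition_matrix(lib)
    dominant = sample_antibody(lib.length, np.random.default_rng(dom_ss))

    results = []
    for case in cases:
        sigma, factor = DOMINANCE_CASES[case]
        rng = np.random.default_rng(run_ss)  # same background draws per case
        q2s, ests = [], []
        for _ in range(reps):
            q2, est = _one_run(
                lib,
                X,
                h,
                n_ab,
                theta,
                rng,
                sigma=sigma,
                dominance_factor=factor,
                dominant=dominant,
                n_components=n_components,
            )
            q2s.append(q2)
            ests.append(est)
        prs = list(pairwise_aaws_correlation(ests)) if reps > 1 else []
        results.append(
            DominanceResult(
                case=case,
                sigma=sigma,
                dominance_factor=factor,
                q2_samples=q2s,
                pairwise_r_samples=prs,
            )
        )
    return results


def pca_aaws(W: np.ndarray, k: int = 2, scale: bool = False) -> PcaResult:
    """Project a collection of weight vectors onto principal components.

    Columns are mean-centred (optionally also scaled to unit variance); the
    returned scores are (n_samples, k), loadings (20, k) and
    variance-explained fractions non-increasing with sum <= 1.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] != 20:
        raise ValueError("W must be (n_samples, 20)")
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    if k > min(n - 1, 20):
        raise ValueError(f"k={k} exceeds available components")
    Z = W - W.mean(axis=0)
    if scale:
        sd = Z.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = Z / sd
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Z)
    return PcaResult(
        scores=scores,
        variance_explained=pca.explained_variance_ratio_,
        loadings=pca.components_.T,
    )


def correlate_with_scale(
    w_avg: np.ndarray, scale_table: pd.DataFrame, method: str = "pearson"
) -> dict[str, float]:
    """Correlate an averaged weight vector with per-amino-acid property
    scales (hydrophilicity, z-scales, antigenicity, ...).

    ``scale_table`` must be indexed by the 20 one-letter amino-acid codes
    (any order) with one column per scale; returns one correlation per
    column, aligned on the canonical alphabet.
    """
    w_avg = np.asarray(w_avg, dtype=float)
    if w_avg.shape != (20,):
        raise ValueError("w_avg must be a 20-vector")
    idx = [str(i).upper() for i in scale_table.index]
    missing = sorted(set(ALPHABET) - set(idx))
    if missing:
        raise ValueError(f"scale table missing amino acid(s): {missing}")
    table = scale_table.copy()
    table.index = idx
    table = table.loc[list(ALPHABET)]
    out: dict[str, float] = {}
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            raise ValueError(f"scale column {col!r} is constant; correlation undefined")
        if method == "pearson":
            out[col] = float(stats.pearsonr(w_avg, vals)[0])
        elif method == "spearman":
            out[col] = float(stats.spearmanr(w_avg, vals)[0])
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
    return out


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided, non-paired Wilcoxon rank-sum p-value for two groups
    (significance is conventionally read at p < 0.05)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
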