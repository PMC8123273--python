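"""Feature screening and extraction: KS normality, Friedman test, PCA.

The HRV indexes are heavily non-normal, so state differences are tested
with the Friedman rank test on matched blocks: each block is one
(participant, window-index) pair observed once in each of the three
session periods, i.e. once per fatigue state.  Features whose Friedman p
falls below alpha are retained; principal components of the retained
(standardized) features are extracted until the cumulative contribution
rate reaches 85%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import permutations, product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "KSResult", "FriedmanResult", "PCAModel", "SelectionResult",
    "ks_normality", "friedman_test", "friedman_exact_permutation_pvalue",
    "select_features", "fit_pca", "transform_pca",
]


class DegenerateInputError(ValueError):
    """Raised for inputs with no variance where variance is required."""


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    reject: bool
    alpha: float


def ks_normality(values, alpha: float = 0.05, lilliefors_correction: bool = True) -> KSResult:
    """One-sample KS test of normality with estimated mean/SD.

    With ``lilliefors_correction`` the p-value accounts for the
    parameters being estimated from the same sample (the appropriate
    reference distribution); without it a plain KS test against the
    fitted normal is run.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 values for the normality screen")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant column: normality test undefined")
    if lilliefors_correction:
        stat, p = lilliefors(x, dist="norm")
    else:
        stat, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return KSResult(statistic=float(stat), p_value=float(p),
                    reject=bool(p < alpha), alpha=alpha)


@dataclass
class FriedmanResult:
    m: int                      # treatments (fatigue states)
    n: int                      # matched blocks
    rank_sums: np.ndarray
    mean_ranks: np.ndarray
    statistic: float
    df: int
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _midranks(blocks: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, blocks)


def friedman_statistic(blocks: np.ndarray, tie_correction: bool = True) -> tuple:
    """Friedman chi-square from an n x m matrix of matched observations.

    The uncorrected statistic is

        X2 = 12 / (n m (m+1)) * sum_j Rj^2 - 3 n (m+1)

    with Rj the column rank sums of within-block midranks; the
    tie-corrected variant divides the rank-sum deviance by the observed
    rank variance and reduces to the same value when no ties occur.
    """
    blocks = np.asarray(blocks, dtype=float)
    n, m = blocks.shape
    ranks = _midranks(blocks)
    rj = ranks.sum(axis=0)
    if tie_correction:
        denom = float((ranks ** 2).sum()) - n * m * (m + 1) ** 2 / 4.0
        if denom == 0:  # every block fully tied
            return 0.0, rj
        x2 = (m - 1) * float(np.sum((rj - n * (m + 1) / 2.0) ** 2)) / denom
    else:
        x2 = 12.0 / (n * m * (m + 1)) * float(np.sum(rj ** 2)) - 3.0 * n * (m + 1)
    return float(x2), rj


def friedman_test(blocks, tie_correction: bool = True, alpha: float = 0.05) -> FriedmanResult:
    """Friedman rank test over complete matched blocks (rows)."""
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ValueError("blocks must be a 2-D matrix (blocks x treatments)")
    n, m = blocks.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    if not np.all(np.isfinite(blocks)):
        raise ValueError("blocks must be complete (no missing values)")
    x2, rj = friedman_statistic(blocks, tie_correction)
    df = m - 1
    p = float(stats.chi2.sf(x2, df))
    return FriedmanResult(m=m, n=n, rank_sums=rj, mean_ranks=rj / n,
                          statistic=x2, df=df, p_value=p, alpha=alpha)


def friedman_exact_permutation_pvalue(blocks, tie_correction: bool = True,
                                      max_blocks: int = 7) -> float:
    """Exact permutation p-value by enumerating all (m!)^n within-block
    treatment rearrangements; feasible only for small n."""
    blocks = np.asarray(blocks, dtype=float)
    n, m = blocks.shape
    if n > max_blocks:
        raise ValueError(f"exact enumeration limited to {max_blocks} blocks")
    obs, _ = friedman_statistic(blocks, tie_correction)
    perms = list(permutations(range(m)))
    count = 0
    total = 0
    for arrangement in product(perms, repeat=n):
        permuted = np.vstack([blocks[i, list(arrangement[i])] for i in range(n)])
        stat, _ = friedman_statistic(permuted, tie_correction)
        count += stat >= obs - 1e-12
        total += 1
    return count / total


@dataclass
class SelectionResult:
    selected: list
    results: dict                 # feature -> FriedmanResult
    report: pd.DataFrame
    excluded_constant: list = field(default_factory=list)


def build_blocks(table: pd.DataFrame, feature: str) -> np.ndarray:
    """Matched blocks for one feature: rows are (participant,
    window_index) pairs, columns the three states."""
    pivot = table.pivot_table(index=["participant", "window_index"],
                              columns="state", values=feature, aggfunc="first")
    incomplete = pivot[pivot.isna().any(axis=1)]
    if len(incomplete):
        raise ValueError(
            "blocks missing a state: " +
            ", ".join(str(i) for i in incomplete.index[:10].tolist()))
    return pivot.to_numpy()


def select_features(table: pd.DataFrame, features=None, alpha: float = 0.05,
                    tie_correction: bool = True) -> SelectionResult:
    """Friedman-test screen of every feature across the three states.

    ``table`` must carry ``participant``, ``window_index`` and ``state``
    columns plus the feature columns.  Constant features are excluded
    with a warning.  The report mirrors the per-state mean / SD / mean
    rank layout used for repeated-measures summaries.
    """
    meta = {"participant", "window_index", "state", "period"}
    if features is None:
        features = [c for c in table.columns if c not in meta]
    states = sorted(table["state"].unique())
    if len(states) < 2:
        raise ValueError("need at least two states")
    results: dict = {}
    rows = []
    selected = []
    excluded = []
    for feat in features:
        col = table[feat].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            warnings.warn(f"feature {feat} is constant; excluded from selection",
                          stacklevel=2)
            excluded.append(feat)
            continue
        blocks = build_blocks(table, feat)
        res = friedman_test(blocks, tie_correction=tie_correction, alpha=alpha)
        results[feat] = res
        if res.significant:
            selected.append(feat)
        for si, s in enumerate(states):
            vals = table.loc[table["state"] == s, feat]
            rows.append({"feature": feat, "state": s,
                         "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                         "mean_rank": float(res.mean_ranks[si]),
                         "chi_square": res.statistic, "df": res.df,
                         "p_value": res.p_value,
                         "selected": res.significant})
    report = pd.DataFrame(rows)
    return SelectionResult(selected=selected, results=results, report=report,
                           excluded_constant=excluded)


@dataclass
class PCAModel:
    """Correlation-matrix PCA with an 85% cumulative-contribution cutoff.

    Loadings follow l_kd = sqrt(lambda_d) * u_kd; the sign of each
    eigenvector is fixed so its largest-magnitude element is positive.
    """

    feature_names: list
    means: np.ndarray
    scales: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray      # columns are components
    contribution: np.ndarray
    cumulative: np.ndarray
    retained: int

    @property
    def loadings(self) -> np.ndarray:
        return self.eigenvectors * np.sqrt(self.eigenvalues)

    def to_json(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "retained": int(self.retained),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            d = json.load(fh)
        ev = np.asarray(d["eigenvalues"])
        contribution = ev / ev.sum()
        return cls(feature_names=d["feature_names"],
                   means=np.asarray(d["means"]), scales=np.asarray(d["scales"]),
                   eigenvalues=ev, eigenvectors=np.asarray(d["eigenvectors"]),
                   contribution=contribution, cumulative=np.cumsum(contribution),
                   retained=int(d["retained"]))


def fit_pca(table: pd.DataFrame, features=None, cum_threshold: float = 0.85) -> PCAModel:
    """Eigendecomposition of the feature correlation matrix.

    Retains the smallest number of components whose cumulative
    contribution rate reaches ``cum_threshold``.
    """
    if features is None:
        meta = {"participant", "window_index", "state", "period"}
        features = [c for c in table.columns if c not in meta]
    x = table[list(features)].to_numpy(dtype=float)
    if x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("PCA needs >= 2 features and >= 3 rows")
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1)
    zero = scales == 0
    if zero.any():
        bad = [f for f, z in zip(features, zero) if z]
        raise DegenerateInputError(f"zero-variance feature(s): {bad}")
    z = (x - means) / scales
    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-magnitude element of each component positive
    for d in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, d]))
        if eigvecs[k, d] < 0:
            eigvecs[:, d] *= -1
    contribution = eigvals / eigvals.sum()
    cumulative = np.cumsum(contribution)
    retained = int(np.searchsorted(cumulative, cum_threshold - 1e-12) + 1)
    return PCAModel(feature_names=list(features), means=means, scales=scales,
                    eigenvalues=eigvals, eigenvectors=eigvecs,
                    contribution=contribution, cumulative=cumulative,
                    retained=retained)


def transform_pca(model: PCAModel, table: pd.DataFrame, n_components: int | None = None,
                  keep_meta: bool = True) -> pd.DataFrame:
    """Project rows on the retained components using training means/scales."""
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise ValueError(f"feature mismatch: missing {missing}")
    k = n_components if n_components is not None else model.retained
    x = table[model.feature_names].to_numpy(dtype=float)
    z = (x - model.means) / model.scales
    scores = z @ model.eigenvectors[:, :k]
    out = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(k)],
                       index=table.index)
    if keep_meta:
        for c in ("participant", "window_index", "state", "period"):
            if c in table.columns:
                out[c] = table[c].to_numpy()
    return out


def inverse_transform_pca(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Map component scores back to the standardized feature space."""
    scores = np.asarray(scores, dtype=float)
    k = scores.shape[1]
    return scores @ model.eigenvectors[:, :k].T
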