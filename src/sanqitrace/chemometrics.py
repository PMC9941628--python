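"""Climate-factor screening, content summaries, PCA, and PLSR with VIP.

The chemometric workflow relates the four quality-marker saponins of
*P. notoginseng* (NG-R1, G-Rg1, G-Rb1, G-Rd, in mg/g) to WorldClim
bioclimatic variables:

1. `pearson_screen` removes collinear climate factors (|R| above a
   threshold, default 0.8) by greedy elimination.
2. `saponin_summary` tabulates per-origin mean +/- SD of each saponin and
   a "total" column (the mean of the four per-saponin group means).
3. `pca_fit` runs PCA on centered+scaled contents (variance criterion:
   keep components until cumulative explained variance > 80%).
4. `plsr_fit` regresses one saponin on the retained factors by partial
   least squares, reports the back-transformed linear equation, and the
   per-factor VIP (variable importance in projection) scores, whose
   squares average to 1; `vip_select` keeps factors with VIP > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .synthetic import BIO_VARS, SAPONINS

__all__ = [
    "pearson_screen",
    "saponin_summary",
    "pca_fit",
    "plsr_fit",
    "vip_select",
    "select_n_components",
    "round_half_up",
    "PCAResult",
    "VIPResult",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as printed reports use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _bio_sort_key(name: str) -> tuple[int, str]:
    digits = "".join(ch for ch in name if ch.isdigit())
    return (int(digits) if digits else 0, name)


def pearson_screen(
    table: pd.DataFrame,
    threshold: float = 0.8,
    variables: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop collinear climate factors by greedy Pearson elimination.

    While any retained pair has |R| > ``threshold``, the pair with the
    largest |R| is found and the member with the larger mean absolute
    correlation to all other retained variables is dropped (tie: the
    higher-numbered Bio variable).  Constant columns have no defined
    correlation and are dropped up front with a warning.

    Returns the retained variable list (original column order) and the
    full correlation matrix over the non-constant candidates.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if variables is None:
        variables = [c for c in table.columns if c.startswith("Bio")]
    if len(table) < 3:
        raise ValueError("need at least 3 rows for correlation screening")
    usable = []
    for v in variables:
        if np.std(table[v].to_numpy(dtype=float)) == 0.0:
            warnings.warn(f"constant column '{v}' dropped: correlation undefined")
        else:
            usable.append(v)
    corr = table[usable].corr(method="pearson")
    retained = list(usable)
    while len(retained) > 1:
        sub = corr.loc[retained, retained].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= threshold:
            break
        mean_i = sub[i].sum() / (len(retained) - 1)
        mean_j = sub[j].sum() / (len(retained) - 1)
        if mean_i > mean_j:
            drop = retained[i]
        elif mean_j > mean_i:
            drop = retained[j]
        else:
            drop = max(retained[i], retained[j], key=_bio_sort_key)
        retained.remove(drop)
    return retained, corr


def saponin_summary(
    table: pd.DataFrame, saponins: tuple[str, ...] = SAPONINS
) -> pd.DataFrame:
    """Per-group mean +/- SD of each saponin plus a total column.

    SD is the sample standard deviation (n-1 denominator); a group of
    size 1 reports SD 0 and is flagged in the ``singleton`` column.  The
    ``total`` column is the arithmetic mean of the four per-saponin group
    means, rounded half-up to 2 decimals as in printed content tables.
    """
    if "group" not in table.columns:
        raise ValueError("table needs a 'group' column")
    rows = []
    for group, g in table.groupby("group", sort=False):
        if len(g) == 0:
            raise ValueError(f"empty group '{group}'")
        row: dict = {"group": group, "n": len(g), "singleton": len(g) == 1}
        means = []
        for s in saponins:
            vals = g[s].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"missing {s} value in group '{group}'")
            m = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[f"{s}_mean"] = m
            row[f"{s}_sd"] = sd
            means.append(m)
        row["total"] = round_half_up(float(np.mean(means)), 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # (n_features, n_components), orthonormal columns
    explained_variance_pct: np.ndarray  # over all components, sums to 100
    n_components: int
    feature_names: list[str]


def pca_fit(
    X: pd.DataFrame | np.ndarray, n_components: int | None = None
) -> PCAResult:
    """PCA of centered and scaled data (correlation-matrix PCA).

    ``explained_variance_pct`` is reported for *all* components so the
    cumulative-variance criterion can be applied by the caller;
    ``n_components`` defaults to the full rank.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    A = np.asarray(X, dtype=float)
    n, p = A.shape
    k = p if n_components is None else int(n_components)
    if not 1 <= k <= p:
        raise ValueError(f"n_components must be in [1, {p}]")
    if n < k:
        raise ValueError("need at least as many rows as requested components")
    sd = A.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance column under scaling: {names[zero[0]]}")
    Z = (A - A.mean(axis=0)) / sd
    pca = PCA(n_components=p, svd_solver="full")
    scores = pca.fit_transform(Z)
    total = pca.explained_variance_.sum()
    pct = 100.0 * pca.explained_variance_ / total
    return PCAResult(
        scores=scores[:, :k],
        loadings=pca.components_[:k].T,
        explained_variance_pct=pct,
        n_components=k,
        feature_names=names,
    )


@dataclass
class VIPResult:
    """A fitted PLS regression of one saponin on screened climate factors."""

    response: str
    predictors: list[str]
    coefficients: np.ndarray  # intercept followed by raw-unit slopes
    vip: np.ndarray  # per-predictor importance, sum of squares == p
    n_components: int

    def equation(self, ndigits: int = 3) -> str:
        terms = [f"{self.coefficients[0]:.{ndigits}f}"]
        for name, b in zip(self.predictors, self.coefficients[1:]):
            terms.append(f"{b:+.{ndigits}f} {name}")
        return f"{self.response}: Y=" + "".join(terms)


def _vip_scores(pls: PLSRegression) -> np.ndarray:
    # standard w-normalized projection formula:
    # vip_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a )
    W = pls.x_weights_  # (p, A)
    T = pls.x_scores_  # (n, A)
    Q = pls.y_loadings_  # (1, A)
    p = W.shape[0]
    ssy = (T**2).sum(axis=0) * (Q[0] ** 2)  # y-variance captured per component
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())


def select_n_components(
    X: np.ndarray, y: np.ndarray, max_components: int, target_r2: float = 0.95
) -> int:
    """Smallest component count whose leave-one-out CV R^2 reaches target."""
    n = X.shape[0]
    ss_tot = float(((y - y.mean()) ** 2).sum())
    for k in range(1, max_components + 1):
        press = 0.0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            m = PLSRegression(n_components=k, scale=True)
            m.fit(X[mask], y[mask].reshape(-1, 1))
            press += float((m.predict(X[i : i + 1]).ravel()[0] - y[i]) ** 2)
        if 1.0 - press / ss_tot >= target_r2:
            return k
    return max_components


def plsr_fit(
    table: pd.DataFrame,
    response: str,
    predictors: list[str] | None = None,
    n_components: int | None = None,
) -> VIPResult:
    """Fit a PLS regression and report the raw-unit linear equation + VIP.

    Latent variables are extracted on standardized predictors and centered
    response; the reported coefficients are back-transformed so that
    ``y = b0 + sum_j b_j * Bio_j`` in the original units.  With
    ``n_components`` equal to the number of predictors on full-rank data,
    PLS coincides with ordinary least squares.  When ``n_components`` is
    None the smallest count reaching 95% leave-one-out explained variance
    is used (capped at p).
    """
    predictors = list(BIO_VARS) if predictors is None else list(predictors)
    p = len(predictors)
    X = table[predictors].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    if n_components is None:
        k = select_n_components(X, y, max_components=p)
    else:
        k = int(n_components)
        if not 1 <= k <= p:
            raise ValueError(f"n_components must be in [1, {p}]")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) <= k:
        raise ValueError(
            f"design is rank-deficient for {k} components on {p} predictors"
        )
    pls = PLSRegression(n_components=k, scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on near-exact fits
        pls.fit(X, y.reshape(-1, 1))
    slopes = pls.coef_.ravel()  # raw-unit slopes (sklearn back-transforms)
    intercept = float(y.mean() - X.mean(axis=0) @ slopes)
    return VIPResult(
        response=response,
        predictors=predictors,
        coefficients=np.concatenate([[intercept], slopes]),
        vip=_vip_scores(pls),
        n_components=k,
    )


def vip_select(result: VIPResult, cutoff: float = 1.0) -> list[str]:
    """Variables with VIP strictly above ``cutoff``, sorted descending."""
    order = np.argsort(-result.vip, kind="stable")
    return [result.predictors[i] for i in order if result.vip[i] > cutoff]
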