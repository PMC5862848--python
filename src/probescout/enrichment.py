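"""Feature-count enrichment: voom precision weights + moderated t-tests.

Specific probe targets are separated from background binders by comparing,
per protein, the number of MS features (unique peptide form x charge state)
observed under the probe condition against a negative-control condition.
Counts are overdispersed, so the comparison follows the voom approach used
for RNA-Seq counts: log2 counts-per-million are modeled with an ordinary
linear model, a lowess trend of sqrt(residual sd) against average log-count
supplies per-observation precision weights, and per-protein variances are
shrunk by empirical Bayes before forming moderated t statistics

    y_ij = log2((c_ij + 0.5) / (N_j + 1) * 1e6)
    w_ij = trend(log2 fitted count)^-4
    s~_i^2 = (d0 s0^2 + d_i s_i^2) / (d0 + d_i),   t_i ~ t(d0 + d_i)

where the prior degrees of freedom d0 and prior variance s0^2 are estimated
by moment-matching the distribution of log s_i^2 (a scaled F under the
hierarchical model).  p-values are Benjamini-Hochberg adjusted.

The module is organised as a model object: build :class:`FeatureEnrichment`
from a count matrix plus sample metadata, call :meth:`FeatureEnrichment.fit`,
and read estimates off the returned :class:`EnrichmentResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

from .site_id import PSM

_SD_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# feature counting


def count_features(psms: Sequence[PSM]) -> pd.DataFrame:
    """Per-protein, per-sample counts of unique (sequence, mods, charge) forms."""
    feats: dict[tuple[str, str], set] = {}
    for psm in psms:
        mod_key = tuple(sorted((pos, mod.name) for pos, mod in psm.mods))
        feats.setdefault((psm.protein_id, psm.sample_id), set()).add(
            (psm.peptide.sequence, mod_key, psm.charge)
        )
    if not feats:
        return pd.DataFrame()
    counts = {k: len(v) for k, v in feats.items()}
    ser = pd.Series(counts)
    ser.index.names = ["protein_id", "sample_id"]
    return ser.unstack(fill_value=0)


def filter_min_features(counts: pd.DataFrame, min_total: int = 3) -> pd.DataFrame:
    """Drop proteins with fewer than ``min_total`` features summed over samples."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    return counts.loc[counts.sum(axis=1) >= min_total]


# ---------------------------------------------------------------------------
# voom transform


@dataclass
class VoomTransform:
    """log2-CPM values, precision weights, and the fitted mean-variance trend."""

    y: np.ndarray  # proteins x samples log2 counts-per-million
    weights: np.ndarray  # same shape, > 0
    trend_x: np.ndarray  # average log2 count per protein
    trend_y: np.ndarray  # sqrt residual sd per protein
    lib_sizes: np.ndarray


def _ols_fit(y: np.ndarray, design: np.ndarray):
    """Row-wise OLS of y on a shared design; returns coefs, residual sd, fitted."""
    pinv = np.linalg.pinv(design)
    coefs = y @ pinv.T  # proteins x p
    fitted = coefs @ design.T
    resid = y - fitted
    dof = y.shape[1] - np.linalg.matrix_rank(design)
    sigma = np.sqrt((resid**2).sum(axis=1) / dof)
    return coefs, sigma, fitted


def voom(
    counts: pd.DataFrame | np.ndarray,
    design: np.ndarray,
    span: float = 0.5,
) -> VoomTransform:
    """Compute log2-CPM and precision weights from the mean-variance trend.

    ``design`` is samples x p (intercept + condition indicator for the
    two-group comparison).  Requires at least two samples per design cell so
    residual degrees of freedom are positive.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2:
        raise ValueError("counts must be 2-D (proteins x samples)")
    design = np.asarray(design, dtype=float)
    n_samples = c.shape[1]
    if design.shape[0] != n_samples:
        raise ValueError("design rows must equal number of samples")
    if n_samples - np.linalg.matrix_rank(design) < 1:
        raise ValueError("fewer than 2 samples per condition: no residual df")

    lib = c.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every retained sample needs a positive library size")
    y = np.log2((c + 0.5) / (lib + 1.0) * 1e6)

    coefs, sigma, fitted = _ols_fit(y, design)
    # mean-variance trend: sqrt-sd vs average log2 count
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(np.maximum(sigma, _SD_FLOOR))

    if np.allclose(sigma, 0.0):
        # degenerate: no residual variation anywhere; flat unit weights
        warnings.warn("all residual variances ~0; using unit voom weights")
        w = np.ones_like(y)
        return VoomTransform(y, w, sx, sy, lib)

    smoothed = sm_lowess(sy, sx, frac=span, it=3, return_sorted=True)
    lx, ly = smoothed[:, 0], smoothed[:, 1]

    fitted_cpm = 2.0**fitted
    fitted_count = 1e-6 * fitted_cpm * (lib + 1.0)
    fitted_logcount = np.log2(fitted_count)
    interp = np.interp(fitted_logcount, lx, ly)
    w = np.maximum(interp, _SD_FLOOR) ** -4
    return VoomTransform(y, w, sx, sy, lib)


# ---------------------------------------------------------------------------
# weighted linear fit + empirical Bayes moderation


@dataclass
class ModeratedFit:
    """Per-protein weighted-fit statistics after empirical-Bayes moderation."""

    coef: np.ndarray  # log2 fold change (condition contrast)
    stdev_unscaled: np.ndarray  # unscaled SE of the contrast
    sigma2: np.ndarray  # raw residual variances
    df_residual: float
    d0: float  # prior df (may be inf)
    s0_2: float  # prior variance
    sigma2_post: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_total: float


def _wls_contrast(y: np.ndarray, w: np.ndarray, design: np.ndarray, coef_idx: int):
    """Row-wise WLS with per-row weights; returns contrast, unscaled SE, s^2."""
    n, p = design.shape
    G = y.shape[0]
    beta = np.empty((G, p))
    unscaled = np.empty(G)
    s2 = np.empty(G)
    dof = n - p
    for g in range(G):
        sw = np.sqrt(w[g])
        Xw = design * sw[:, None]
        yw = y[g] * sw
        xtx = Xw.T @ Xw
        xtx_inv = np.linalg.inv(xtx)
        b = xtx_inv @ (Xw.T @ yw)
        resid = yw - Xw @ b
        beta[g] = b
        s2[g] = (resid**2).sum() / dof
        unscaled[g] = np.sqrt(xtx_inv[coef_idx, coef_idx])
    return beta, unscaled, s2, dof


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log s^2 to a scaled F to get prior df d0 and variance s0^2.

    Solves trigamma(d0/2) = var(log s^2) - trigamma(df/2); returns
    (inf, geometric-mean variance) when the observed spread is no larger than
    expected under a single common variance.
    """
    s2 = np.maximum(s2, _SD_FLOOR**2)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if not np.isfinite(evar) or evar <= 0:
        warnings.warn(
            "near-equal residual variances; falling back to common variance "
            "(prior df = inf)"
        )
        return np.inf, float(np.exp(emean))
    d0_half = _trigamma_inverse(evar)
    d0 = 2.0 * d0_half
    s0_2 = float(np.exp(emean + special.digamma(d0_half) - np.log(d0_half)))
    return float(d0), s0_2


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    y = 0.5 + 1.0 / x  # starting value; trigamma(y) ~ 1/y for large y
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderated_t(
    transform: VoomTransform,
    design: np.ndarray,
    coef_idx: int = 1,
    d0_override: float | None = None,
) -> ModeratedFit:
    """Weighted least squares per protein + empirical-Bayes moderated t-test.

    ``coef_idx`` selects the tested coefficient (default: the condition
    indicator in an intercept + condition design).  ``d0_override`` forces the
    prior degrees of freedom (0 recovers the ordinary per-protein t-test;
    inf the common-variance limit).
    """
    design = np.asarray(design, dtype=float)
    beta, unscaled, s2, dof = _wls_contrast(
        transform.y, transform.weights, design, coef_idx
    )
    if dof < 1:
        raise ValueError("each protein needs residual df >= 1")
    if np.allclose(s2, 0.0):
        raise ValueError("all residual variances are zero; cannot moderate")

    if d0_override is not None:
        d0 = float(d0_override)
        s0_2 = float(np.exp(np.mean(np.log(np.maximum(s2, _SD_FLOOR**2)))))
    else:
        d0, s0_2 = _fit_f_dist(s2, dof)

    if np.isinf(d0):
        sigma2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        sigma2_post = (d0 * s0_2 + dof * s2) / (d0 + dof)
        df_total = d0 + dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, coef_idx] / (unscaled * np.sqrt(sigma2_post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return ModeratedFit(
        coef=beta[:, coef_idx],
        stdev_unscaled=unscaled,
        sigma2=s2,
        df_residual=float(dof),
        d0=d0,
        s0_2=s0_2,
        sigma2_post=sigma2_post,
        t=t,
        p=p,
        df_total=df_total,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# model / results objects


class FeatureEnrichment:
    """Two-condition feature-count enrichment model (probe vs control).

    Parameters
    ----------
    counts : DataFrame
        Proteins x samples integer feature counts.
    metadata : DataFrame
        One row per sample with columns ``sample_id, condition, replicate``;
        ``condition`` takes values ``probe`` / ``control``.
    min_total_features : int
        Proteins with fewer total features than this are discarded before
        fitting (default 3).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        min_total_features: int = 3,
    ):
        meta = metadata.set_index("sample_id").loc[list(counts.columns)]
        bad = set(meta["condition"]) - {"probe", "control"}
        if bad:
            raise ValueError(f"unknown condition label(s): {sorted(bad)}")
        for cond in ("probe", "control"):
            if (meta["condition"] == cond).sum() < 2:
                raise ValueError(f"condition {cond!r} needs >= 2 samples")
        self.counts = filter_min_features(
            counts.astype(int), min_total_features
        )
        self.metadata = meta
        self.design = np.column_stack(
            [
                np.ones(len(meta)),
                (meta["condition"] == "probe").to_numpy(float),
            ]
        )

    @classmethod
    def from_files(cls, counts_tsv, metadata_tsv, **kwargs) -> "FeatureEnrichment":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0, comment="#")
        meta = pd.read_csv(metadata_tsv, sep="\t", comment="#")
        return cls(counts, meta, **kwargs)

    def fit(self, span: float = 0.5, d0_override: float | None = None):
        vt = voom(self.counts, self.design, span=span)
        mf = moderated_t(vt, self.design, coef_idx=1, d0_override=d0_override)
        q = bh_adjust(mf.p)
        return EnrichmentResults(self, vt, mf, q)


class EnrichmentResults:
    """Fitted enrichment results: per-protein log2FC, moderated t, p, q."""

    def __init__(self, model, transform, fit, q):
        self.model = model
        self.transform = transform
        self.fit_ = fit
        self.q = q
        self.proteins = list(model.counts.index)

    @property
    def log2_fold_change(self) -> np.ndarray:
        return self.fit_.coef

    @property
    def p_values(self) -> np.ndarray:
        return self.fit_.p

    def as_frame(
        self, site_flags: Mapping[str, bool] | None = None
    ) -> pd.DataFrame:
        """Volcano-plot table: one row per protein, sorted by q then |log2FC|."""
        df = pd.DataFrame(
            {
                "protein_id": self.proteins,
                "log2FC": self.fit_.coef,
                "t": self.fit_.t,
                "p": self.fit_.p,
                "q": self.q,
                "neg_log10_p": -np.log10(self.fit_.p),
                "mean_feature_count": self.model.counts.mean(axis=1).to_numpy(),
            }
        )
        df["high_confidence_site"] = (
            df["protein_id"].map(lambda p: bool(site_flags.get(p, False)))
            if site_flags is not None
            else False
        )
        df["zero_residual"] = self.fit_.sigma2 <= _SD_FLOOR**2 * 10
        df["_absfc"] = df["log2FC"].abs()
        df = df.sort_values(
            ["q", "_absfc"], ascending=[True, False], kind="mergesort"
        ).drop(columns="_absfc")
        return df.reset_index(drop=True)

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        n_sig = int((self.q < 0.05).sum())
        lines = [
            "Feature-count enrichment (voom + moderated t)",
            "=" * 46,
            f"proteins tested:        {len(self.proteins)}",
            f"samples:                {self.model.design.shape[0]} "
            f"({int(self.model.design[:, 1].sum())} probe)",
            f"prior df (d0):          {self.fit_.d0:.3g}",
            f"prior variance (s0^2):  {self.fit_.s0_2:.4g}",
            f"residual df per protein:{self.fit_.df_residual:.0f}",
            f"proteins with q < 0.05: {n_sig}",
        ]
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """Volcano plot: -log10 p against log2 fold change."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sig = self.q < 0.05
        ax.scatter(
            self.fit_.coef[~sig], -np.log10(self.fit_.p[~sig]), s=8, c="grey"
        )
        ax.scatter(
            self.fit_.coef[sig], -np.log10(self.fit_.p[sig]), s=8, c="crimson"
        )
        ax.set_xlabel("log2 fold change (probe / control)")
        ax.set_ylabel("-log10 p")
        return ax


def volcano_table(results: EnrichmentResults, **kwargs) -> pd.DataFrame:
    """Functional alias for :meth:`EnrichmentResults.as_frame`."""
    return results.as_frame(**kwargs)
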