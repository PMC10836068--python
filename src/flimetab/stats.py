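"""Distribution-level metabolic statistics on fitted parameter maps.

Covers the figure-style analyses run on a1 / tau_m maps: pooled value
extraction under the tumor mask, single vs bimodal Gaussian description of
the a1 distribution (a bimodal a1 histogram indicates two coexisting
metabolic subpopulations in one tumor), per-fish summaries, and group
comparisons (unpaired two-tailed t-tests on per-fish means; two-way ANOVA
on group x histogram-bin relative frequencies).

Mixture fitting operates on raw per-pixel values by maximum likelihood
rather than on binned histogram counts: it is the statistically cleaner
equivalent of fitting Gaussians to a histogram. Model order (1 vs 2) is
selected by BIC with a parsimony tie-break (delta BIC < 2 keeps the
single Gaussian).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DegenerateSampleError, EmptySelectionError
from .pixelfit import ROIMask
from .synth import ParameterMaps

A1_BIN_WIDTH = 0.01  # histogram bin width for a1 in [0, 1]


@dataclass
class MixtureModel:
    """Gaussian mixture with k = 1 or 2 components, means ascending."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float
    aic: float
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": [float(w) for w in self.weights],
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
            "log_likelihood": float(self.log_likelihood),
            "bic": float(self.bic),
            "aic": float(self.aic),
            "converged": bool(self.converged),
        }


@dataclass
class ModalitySelection:
    """Outcome of the 1-vs-2 component model comparison."""

    k: int
    model_k1: MixtureModel
    model_k2: MixtureModel
    delta_bic: float  # BIC(k=1) - BIC(k=2); >= 2 selects the bimodal model


@dataclass
class GroupComparison:
    """Result of a two-group statistical test."""

    test_name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, int]
    effect_direction: int  # sign of (group A mean - group B mean)

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "group_sizes": list(self.group_sizes),
            "effect_direction": int(self.effect_direction),
        }


def masked_values(maps: ParameterMaps, mask: ROIMask,
                  field: str = "a1") -> pd.DataFrame:
    """Finite fitted values at masked pixels, with pixel provenance.

    Returns a frame with columns ``row``, ``col``, ``value``. Unfit pixels
    (NaN or fit_ok False) are excluded; an empty result raises an
    empty-selection error.
    """
    if field not in ("a1", "tau_m"):
        raise ValueError("field must be 'a1' or 'tau_m'")
    image = getattr(maps, field)
    if mask.include.shape != image.shape:
        raise ValueError("mask and maps shapes differ")
    ok = mask.include & maps.valid_mask() & np.isfinite(image)
    if not ok.any():
        raise EmptySelectionError(
            f"no finite fitted {field} values under the mask")
    rows, cols = np.nonzero(ok)
    return pd.DataFrame({"row": rows, "col": cols, "value": image[ok]})


def fit_mixture(values: Sequence[float], k: int, seed: int = 0,
                n_restarts: int = 10, max_iter: int = 500,
                tol: float = 1e-8) -> MixtureModel:
    """Maximum-likelihood Gaussian mixture of order ``k`` (1 or 2).

    k=1 uses the closed-form Gaussian MLE; k=2 runs EM with
    ``n_restarts`` random initializations (best likelihood kept),
    deterministic given ``seed``. Scores are BIC/AIC with parameter count
    2k + (k - 1).
    """
    x = np.asarray(values, dtype=float)
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    n = x.size
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} values for k={k}, got {n}")
    if np.ptp(x) == 0.0:
        raise DegenerateSampleError("sample has zero variance")
    if k == 1:
        mu = float(x.mean())
        sd = float(x.std())  # MLE (ddof=0)
        ll = float(sps.norm.logpdf(x, mu, sd).sum())
        n_params = 2
        return MixtureModel(1, np.array([1.0]), np.array([mu]),
                            np.array([sd]), ll,
                            bic=n_params * np.log(n) - 2 * ll,
                            aic=2 * n_params - 2 * ll)
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         n_init=n_restarts, init_params="k-means++",
                         max_iter=max_iter, tol=tol, reg_covar=1e-12,
                         random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn convergence chatter
        gm.fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    ll = float(gm.score(x[:, None]) * n)
    return MixtureModel(2, weights, means, sds, ll,
                        bic=float(gm.bic(x[:, None])),
                        aic=float(gm.aic(x[:, None])),
                        converged=bool(gm.converged_))


def select_modality(values: Sequence[float], seed: int = 0) -> ModalitySelection:
    """Choose between a single Gaussian and a two-component mixture.

    Fits both orders and keeps the lower BIC; a BIC advantage of less than
    2 for the mixture is treated as a tie and resolved to the single
    Gaussian (parsimony).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 50:
        raise ValueError(f"need at least 50 values, got {x.size}")
    m1 = fit_mixture(x, 1, seed=seed)
    m2 = fit_mixture(x, 2, seed=seed)
    delta = m1.bic - m2.bic
    k = 2 if delta >= 2.0 else 1
    return ModalitySelection(k=k, model_k1=m1, model_k2=m2,
                             delta_bic=float(delta))


def histogram_table(samples_by_group: dict[str, Sequence[float]],
                    bin_width: float = A1_BIN_WIDTH,
                    value_range: tuple[float, float] = (0.0, 1.0)
                    ) -> pd.DataFrame:
    """Binned relative-frequency table with columns group, bin, frequency.

    Frequencies are normalized within each group (each group's column sums
    to 1), which is the form the two-way ANOVA comparison consumes.
    """
    edges = np.arange(value_range[0], value_range[1] + bin_width / 2,
                      bin_width)
    records = []
    for group, values in samples_by_group.items():
        counts, _ = np.histogram(np.asarray(values, dtype=float), bins=edges)
        freq = counts / max(counts.sum(), 1)
        for b, f in enumerate(freq):
            records.append({"group": group, "bin": b, "frequency": f})
    return pd.DataFrame.from_records(records)


def _ttest(a: np.ndarray, b: np.ndarray) -> GroupComparison:
    if min(a.size, b.size) < 2:
        raise ValueError("t-test needs at least 2 units per group")
    diff = a.mean() - b.mean()
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and diff == 0:
        stat, p = 0.0, 1.0  # identical constant groups
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison("unpaired_t_two_tailed", float(stat), float(p),
                           (a.size, b.size), int(np.sign(diff)))


def _two_way_anova(a: np.ndarray, b: np.ndarray,
                   labels: tuple[str, str]) -> GroupComparison:
    table = histogram_table({labels[0]: a, labels[1]: b})
    fit = smf.ols("frequency ~ C(group) + C(bin)", data=table).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    row = anova.loc["C(group)"]
    diff = float(np.mean(a) - np.mean(b))
    return GroupComparison("two_way_anova", float(row["F"]),
                           float(row["PR(>F)"]),
                           (len(a), len(b)), int(np.sign(diff)))


def compare_groups(group_a: Sequence[float], group_b: Sequence[float],
                   test: str = "unpaired_t_two_tailed",
                   labels: tuple[str, str] = ("A", "B")) -> GroupComparison:
    """Compare two groups of measurements.

    For ``unpaired_t_two_tailed`` the inputs are per-unit (per-fish) mean
    values — the unit of inference is the fish, not the pixel, to avoid
    pseudo-replication. For ``two_way_anova`` the inputs are pooled
    per-pixel values; they are binned into relative-frequency histograms
    and group and histogram-bin act as the two factors.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if test == "unpaired_t_two_tailed":
        return _ttest(a, b)
    if test == "two_way_anova":
        if min(a.size, b.size) < 2:
            raise ValueError("ANOVA needs at least 2 values per group")
        return _two_way_anova(a, b, labels)
    raise ValueError(f"unknown test {test!r}")


def summarize_units(units: Sequence[tuple[str, ParameterMaps, ROIMask]]
                    ) -> pd.DataFrame:
    """Per-unit (per-fish) summary table of masked, fitted pixels.

    Columns: unit, mean_a1, mean_tau_m, n_pixels, ok. Units whose mask
    selects no fitted pixel are flagged (ok=False, NaN means) and should
    be excluded from group tests; a warning is logged for them.
    """
    if not units:
        raise ValueError("need at least one unit")
    rows = []
    for label, maps, mask in units:
        try:
            a1 = masked_values(maps, mask, "a1")["value"]
            tm = masked_values(maps, mask, "tau_m")["value"]
            rows.append({"unit": label, "mean_a1": float(a1.mean()),
                         "mean_tau_m": float(tm.mean()),
                         "n_pixels": int(len(a1)), "ok": True})
        except EmptySelectionError:
            warnings.warn(f"unit {label!r} has no fitted pixels under its "
                          "mask; flagged and excluded from tests",
                          stacklevel=2)
            rows.append({"unit": label, "mean_a1": np.nan,
                         "mean_tau_m": np.nan, "n_pixels": 0, "ok": False})
    return pd.DataFrame.from_records(rows)
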