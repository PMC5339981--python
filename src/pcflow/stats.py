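"""Method-comparison statistics: Pearson r with Fisher CI, Bland-Altman
agreement, comparison of correlation coefficients, and normality screening,
assembled into a per-parameter comparison table (1Dir-vs-reference and
3Dir-vs-reference rows with r, 95% CI, p, bias ± SD, and a comparison-of-r
p-value).

Sign convention throughout: bias = mean(method - reference), so a method
that underestimates the reference shows a negative bias.

The comparison-of-r test defaults to Steiger's Z for dependent overlapping
correlations (both CMR methods are correlated against the same reference in
the same subjects); an independent-samples Fisher-z variant is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PearsonResult",
    "BlandAltmanResult",
    "ComparisonResult",
    "ComparisonTable",
    "pearson_ci",
    "bland_altman",
    "compare_correlations",
    "ks_normality",
    "cohort_table",
    "PARAMETER_SPECS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    """One row of the comparison table."""

    r: float
    ci_low: float
    ci_high: float
    p_r: float
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


def _as_finite(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


def pearson_ci(x, y, *, alpha: float = 0.05) -> PearsonResult:
    """Product-moment correlation with Fisher-z CI and two-sided t-test p.

    CI: tanh(arctanh(r) ± z_{1-alpha/2} / sqrt(n-3)); p from
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = _as_finite(x, "x")
    y = _as_finite(y, "y")
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = sps.pearsonr(x, y)
    r = float(r)
    if n > 3 and abs(r) < 1.0:
        zc = sps.norm.ppf(1.0 - alpha / 2.0)
        z = math.atanh(r)
        se = 1.0 / math.sqrt(n - 3)
        lo, hi = math.tanh(z - zc * se), math.tanh(z + zc * se)
    else:
        lo = hi = r
    return PearsonResult(r=r, ci_low=lo, ci_high=hi, p=float(p), n=n)


def bland_altman(method, reference) -> BlandAltmanResult:
    """Agreement of a method against a reference: bias ± SD of differences.

    d = method - reference; bias = mean(d), sd = sample SD (n-1), limits of
    agreement = bias ± 1.96 sd.
    """
    m = _as_finite(method, "method")
    r = _as_finite(reference, "reference")
    if m.shape != r.shape:
        raise ValueError("method and reference must have equal length")
    if m.size < 2:
        raise ValueError("need at least 2 observations")
    d = m - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        n=m.size,
    )


def compare_correlations(
    r1: float,
    r2: float,
    n: int,
    method: str = "steiger_dependent",
    r12: float | None = None,
) -> float:
    """Two-sided p-value for H0: rho1 = rho2.

    ``fisher_independent``: z = (z1 - z2) / sqrt(2/(n-3)) on Fisher-
    transformed correlations, treating the two as independent.
    ``steiger_dependent``: Steiger's Z for overlapping dependent correlations
    that share one variable, requiring ``r12`` (the correlation between the
    two non-shared variables, here the two CMR methods).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if r1 == r2:
        # Identical observed correlations cannot discriminate, whatever the
        # dependence structure; also covers the degenerate |r| = 1 case.
        return 1.0
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("|r| must be < 1")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    if method == "fisher_independent":
        z = (z1 - z2) / math.sqrt(2.0 / (n - 3))
    elif method == "steiger_dependent":
        if r12 is None:
            raise ValueError("steiger_dependent requires r12")
        rbar2 = ((r1 + r2) / 2.0) ** 2
        psi = r12 * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r12**2)
        c = psi / (1.0 - rbar2) ** 2
        denom = math.sqrt(2.0 - 2.0 * c)
        if denom == 0.0:
            return 1.0 if z1 == z2 else 0.0
        z = math.sqrt(n - 3) * (z1 - z2) / denom
    else:
        raise ValueError("method must be fisher_independent or steiger_dependent")
    return float(2.0 * sps.norm.sf(abs(z)))


def ks_normality(x) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean and SD.

    Because the parameters are estimated from the same data (the Lilliefors
    situation), the asymptotic p-value is conservative; the caveat is logged
    rather than corrected with Lilliefors tables.
    """
    x = _as_finite(x, "x")
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in input")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    logger.info(
        "ks_normality: parameters estimated from the sample (Lilliefors "
        "situation); asymptotic p = %.4g is conservative", p
    )
    return float(stat), float(p)


#: (table row label, per-method column template, reference column).
#: SV is compared against cine SV, AVA variants against the reference
#: continuity-equation AVA; everything else against the reference method.
PARAMETER_SPECS = [
    ("Vmean", "vmean_{m}", "vmean_tte"),
    ("Vpeak", "vpeak_{m}", "vpeak_tte"),
    ("MG", "mg_{m}", "mg_tte"),
    ("PG", "pg_{m}", "pg_tte"),
    ("VTI", "vti_{m}", "vti_tte"),
    ("SV", "sv_{m}", "sv_cine"),
    ("AVA_Cine", "ava_cine_{m}", "ava_tte"),
    ("AVA_Flow", "ava_flow_{m}", "ava_tte"),
]

_METHOD_TAGS = {"1Dir": "1dir", "3Dir": "3dir"}


@dataclass
class ComparisonTable:
    """Per-parameter method-comparison rows, renderable as CSV or text."""

    frame: pd.DataFrame
    n_subjects: int
    severity_filter: str | None = None
    compare_method: str = "steiger_dependent"

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=True)

    def to_text(self) -> str:
        lines = [
            f"Method comparison table (n = {self.n_subjects}"
            + (f", filter = {self.severity_filter}" if self.severity_filter else "")
            + ")",
            f"{'parameter':<10}{'method':<7}{'r':>7}{'95% CI':>17}"
            f"{'p':>10}{'bias':>10}{'SD':>9}{'p(r1=r2)':>10}",
        ]
        for (param, meth), row in self.frame.iterrows():
            lines.append(
                f"{param:<10}{meth:<7}{row['r']:>7.2f}"
                f"{row['ci_low']:>8.2f}-{row['ci_high']:<8.2f}"
                f"{row['p_r']:>10.4f}{row['bias']:>10.2f}{row['sd']:>9.2f}"
                f"{row['p_compare']:>10.4f}"
            )
        return "\n".join(lines)


def cohort_table(
    wide: pd.DataFrame,
    severity_filter: str | list[str] | None = None,
    *,
    compare_method: str = "steiger_dependent",
    min_n: int = 4,
) -> ComparisonTable:
    """Build the per-parameter comparison of both CMR modes with a reference.

    ``wide`` holds one row per subject with columns named per
    :data:`PARAMETER_SPECS` (e.g. ``vpeak_1dir``, ``vpeak_3dir``,
    ``vpeak_tte``, ..., ``sv_cine``, ``ava_tte``) and a ``severity`` column.
    ``severity_filter='moderate_severe'`` restricts to the moderate+severe
    subgroup.
    """
    df = wide
    label = None
    if severity_filter is not None:
        if isinstance(severity_filter, str):
            label = severity_filter
            keep = (
                ["moderate", "severe"]
                if severity_filter == "moderate_severe"
                else [severity_filter]
            )
        else:
            keep = list(severity_filter)
            label = "+".join(keep)
        df = df[df["severity"].isin(keep)]
    if len(df) < min_n:
        raise ValueError(
            f"insufficient subjects after filtering: {len(df)} < {min_n}"
        )

    rows = {}
    for param, tmpl, ref_col in PARAMETER_SPECS:
        cols = [tmpl.format(m=t) for t in _METHOD_TAGS.values()] + [ref_col]
        sub = df[cols].dropna()
        if len(sub) < min_n:
            continue
        ref = sub[ref_col].to_numpy()
        results = {}
        for meth, tag in _METHOD_TAGS.items():
            vals = sub[tmpl.format(m=tag)].to_numpy()
            pr = pearson_ci(vals, ref)
            ba = bland_altman(vals, ref)
            results[meth] = (pr, ba)
        # Degenerate cohorts (no noise, aligned jets) reach |r| = 1 exactly;
        # clip so the Fisher transform stays finite.
        clip = 1.0 - 1e-12
        r1 = float(np.clip(results["1Dir"][0].r, -clip, clip))
        r2 = float(np.clip(results["3Dir"][0].r, -clip, clip))
        r12 = float(np.clip(pearson_ci(
            sub[tmpl.format(m="1dir")].to_numpy(),
            sub[tmpl.format(m="3dir")].to_numpy(),
        ).r, -clip, clip))
        p_cmp = compare_correlations(
            r1, r2, len(sub), method=compare_method,
            r12=r12 if compare_method == "steiger_dependent" else None,
        )
        for meth, (pr, ba) in results.items():
            rows[(param, meth)] = {
                "r": pr.r, "ci_low": pr.ci_low, "ci_high": pr.ci_high,
                "p_r": pr.p, "bias": ba.bias, "sd": ba.sd,
                "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                "n": pr.n, "p_compare": p_cmp,
            }

    if not rows:
        raise ValueError("no parameter had enough complete observations")
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["parameter", "method"])
    return ComparisonTable(
        frame=frame, n_subjects=len(df), severity_filter=label,
        compare_method=compare_method,
    )
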