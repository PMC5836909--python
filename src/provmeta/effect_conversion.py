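"""Conversion of heterogeneous test statistics to Fisher's Zr effect sizes.

Every reported statistic (r, chi-square with 1 df, F with 1 numerator df,
odds ratio, Cohen's d, or a 2x2 contingency table) is first mapped to an
unsigned correlation magnitude, signed by the reported direction of the
provisioning effect, and then transformed to Fisher's Zr = atanh(r) with
sampling variance 1/(n - 3).  Positive Zr means increased infection in
provisioned wildlife.
"""

from __future__ import annotations

import math
import warnings

__all__ = [
    "chi2_to_r",
    "f_to_r",
    "or_to_r",
    "d_to_r",
    "contingency_to_chi2",
    "signed_zr",
    "zr_to_r",
    "classify_effect",
    "derive_effect_sizes",
]

#: |r| values at or above this are clamped before atanh; a perfect
#: association has infinite Zr and would break every downstream model.
R_CLAMP = 0.999999

EFFECT_CLASSES = ("trivial", "small_medium", "medium_large", "large_very_large")


def chi2_to_r(x2: float, n: int) -> float:
    """Correlation magnitude from a 1-df chi-square statistic: r = sqrt(x2/n).

    Values of ``x2`` exceeding ``n`` (impossible for a true phi coefficient,
    but possible with rounded published statistics) are capped at r = 1 with
    a warning.
    """
    if n <= 0:
        raise ValueError("chi2_to_r requires n >= 1")
    if x2 < 0:
        raise ValueError("chi-square statistic must be non-negative")
    r = math.sqrt(x2 / n)
    if r > 1.0:
        warnings.warn(
            f"chi2 ({x2}) exceeds n ({n}); r capped at 1", stacklevel=2
        )
        r = 1.0
    return r


def f_to_r(f: float, df_error: float, df_num: int = 1) -> float:
    """Correlation magnitude from an F statistic with 1 numerator df.

    r = sqrt(F / (F + df_error)); only valid for df_num = 1 (a two-group or
    single-slope contrast).
    """
    if df_num != 1:
        raise ValueError("F-to-r conversion is valid only for numerator df = 1")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if f < 0:
        raise ValueError("F statistic must be non-negative")
    return math.sqrt(f / (f + df_error))


def or_to_r(odds_ratio: float) -> float:
    """Digby's approximation: r = (OR^0.75 - 1) / (OR^0.75 + 1).

    Signed: odds ratios below 1 give negative r, and
    or_to_r(OR) == -or_to_r(1/OR).
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    q = odds_ratio ** 0.75
    return (q - 1.0) / (q + 1.0)


def d_to_r(d: float, n1: int | None = None, n2: int | None = None) -> float:
    """Correlation from a standardized mean difference (Cohen's d).

    r = d / sqrt(d^2 + a) with a = (n1 + n2)^2 / (n1 * n2).  When the group
    sizes are unreported the balanced-group value a = 4 is assumed (logged
    via a warning so the assumption is auditable).
    """
    if (n1 is None) != (n2 is None):
        raise ValueError("supply both group sizes or neither")
    if n1 is None:
        warnings.warn(
            "group sizes unreported; assuming balanced groups (a = 4)",
            stacklevel=2,
        )
        a = 4.0
    else:
        if n1 < 1 or n2 < 1:
            raise ValueError("group sizes must be >= 1")
        a = (n1 + n2) ** 2 / (n1 * n2)
    return d / math.sqrt(d * d + a)


def contingency_to_chi2(
    a: float, b: float, c: float, d: float
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and n from a 2x2 table.

    Rows are provisioned/unprovisioned, columns infected/uninfected.  All
    four margins must be positive; otherwise the association is undefined.
    Counts may be non-integer (e.g. reconstructed from reported prevalences).
    The omission of the Yates correction keeps chi2_to_r(chi2, n) exactly
    equal to the phi coefficient of the table.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("contingency counts must be non-negative")
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m <= 0 for m in margins):
        raise ValueError("zero margin in 2x2 table; association undefined")
    num = n * (a * d - b * c) ** 2
    den = margins[0] * margins[1] * margins[2] * margins[3]
    return num / den, n


def signed_zr(r: float, direction: str, n: int) -> tuple[float, float]:
    """Fisher's Zr and its sampling variance from an unsigned |r|.

    direction 'increase' keeps the positive sign (greater infection with
    provisioning); 'decrease' negates.  v = 1/(n - 3), which requires
    n >= 4.  |r| >= 1 is clamped to R_CLAMP with a warning.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    if n < 4:
        raise ValueError("n must be >= 4 for a positive sampling variance 1/(n-3)")
    r = abs(r)
    if r >= 1.0:
        warnings.warn(
            "perfect association |r| >= 1 clamped before atanh", stacklevel=2
        )
        r = R_CLAMP
    zr = math.atanh(r)
    if direction == "decrease":
        zr = -zr
    return zr, 1.0 / (n - 3)


def zr_to_r(zr: float) -> float:
    """Back-transform Fisher's Zr to a correlation: r = tanh(zr)."""
    return math.tanh(zr)


def classify_effect(r: float) -> str:
    """Cohen-style magnitude class of a correlation.

    |r| < .1 trivial; [.1, .3) small_medium; [.3, .5] medium_large;
    > .5 large_very_large.
    """
    m = abs(r)
    if m > 1.0:
        raise ValueError("|r| must be <= 1")
    if m < 0.1:
        return "trivial"
    if m < 0.3:
        return "small_medium"
    if m <= 0.5:
        return "medium_large"
    return "large_very_large"


def _record_r(rec) -> tuple[float, str]:
    """Unsigned |r| plus a provenance tag for one effect record."""
    kind = rec.stat_kind
    p = rec.stat_payload
    if kind == "r":
        return abs(p["value"]), "r (reported)"
    if kind == "chi2":
        return chi2_to_r(p["value"], rec.n_total), "chi2 -> r = sqrt(x2/n)"
    if kind == "F":
        return (
            f_to_r(p["value"], p["df_error"]),
            "F -> r = sqrt(F/(F+df_error))",
        )
    if kind == "odds_ratio":
        return abs(or_to_r(p["value"])), "OR -> r (Digby approximation)"
    if kind == "cohens_d":
        return (
            abs(d_to_r(p["value"], p.get("n1"), p.get("n2"))),
            "d -> r = d/sqrt(d^2 + (n1+n2)^2/(n1 n2))",
        )
    if kind == "contingency":
        x2, n = contingency_to_chi2(p["a"], p["b"], p["c"], p["d"])
        return chi2_to_r(x2, n), "2x2 table -> chi2 -> r (phi)"
    raise ValueError(f"unknown stat_kind {kind!r}")


def derive_effect_sizes(records, skip_small_n: bool = True):
    """Populate zr / sampling_variance on a collection of EffectRecords.

    Records with n_total < 4 have an undefined sampling variance and are
    left unannotated with a warning (and excluded from modelling
    downstream).  Returns the same record objects, annotated in place, with
    a conversion-provenance tag per row.
    """
    out = []
    for rec in records:
        if rec.n_total < 4:
            if not skip_small_n:
                raise ValueError(
                    f"record {rec.record_id}: n_total < 4, variance undefined"
                )
            warnings.warn(
                f"record {rec.record_id}: n_total={rec.n_total} < 4; "
                "zr/variance left unpopulated",
                stacklevel=2,
            )
            out.append(rec)
            continue
        r, tag = _record_r(rec)
        rec.zr, rec.sampling_variance = signed_zr(r, rec.direction, rec.n_total)
        rec.conversion_note = tag
        out.append(rec)
    return out
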