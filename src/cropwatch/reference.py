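"""Published agreement-regression summaries from the originating field study.

The package's regression machinery can be checked for internal
consistency against the summary statistics published for the South
African commercial-farm field study this package models (n = 10 ten-day
periods).  For a simple regression on n points, R² and the F statistic
on (1, n−2) degrees of freedom are linked by

    R² = F / (F + n − 2),      adj R² = 1 − (1 − R²) (n − 1)/(n − 2),

so each published (F, adj R²) pair can be verified without the raw
data, as can the published p-values from the F(1, n−2) upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

#: n for every published fit: ten ten-day periods.
PUBLISHED_N = 10


@dataclass(frozen=True)
class PublishedFit:
    predictor: str  # method whose event counts predict
    response: str  # researcher measure predicted
    species: str
    adj_r2: float
    residual_se: float
    f_stat: float
    p_printed: str  # as printed, e.g. ".005" or "<.001"


PUBLISHED_FITS = [
    PublishedFit("guard", "crop loss", "baboon", 0.61, 10.7, 14.9, ".005"),
    PublishedFit("camera", "crop loss", "baboon", 0.80, 7.63, 36.9, "<.001"),
    PublishedFit("guard", "events", "baboon", 0.45, 2.29, 8.49, ".020"),
    PublishedFit("camera", "events", "baboon", 0.90, 0.99, 78.6, "<.001"),
    PublishedFit("guard", "crop loss", "vervet", 0.54, 1.58, 11.4, ".010"),
    PublishedFit("camera", "crop loss", "vervet", 0.25, 2.00, 4.04, ".079"),
    PublishedFit("guard", "events", "vervet", 0.69, 0.77, 21.1, ".002"),
    PublishedFit("camera", "events", "vervet", 0.41, 1.06, 7.19, ".028"),
]


def r2_from_f(f_stat: float, n: int) -> float:
    """Invert F = (n−2) R² / (1 − R²) for simple regression."""
    return f_stat / (f_stat + (n - 2))


def adj_r2_from_r2(r2: float, n: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def p_from_f(f_stat: float, n: int) -> float:
    """Upper tail of F(1, n−2) at the observed statistic."""
    return float(stats.f.sf(f_stat, 1, n - 2))


def adj_r2_residuals(n: int = PUBLISHED_N) -> list[float]:
    """Per published row: recomputed-minus-printed adjusted R²."""
    return [
        adj_r2_from_r2(r2_from_f(row.f_stat, n), n) - row.adj_r2
        for row in PUBLISHED_FITS
    ]
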