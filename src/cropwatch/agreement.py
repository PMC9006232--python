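"""Method-agreement regressions between observation methods.

For each species, simple ordinary least squares asks how well the
ten-day-period means of guard- and camera-recorded crop-foraging
events predict (a) researcher-recorded crop loss (items/day) and
(b) researcher-recorded crop-foraging events (events/day): eight fits
in total, reported with the standard simple-regression summary columns
(adjusted R², residual standard error, F statistic, p-value).

The module exposes both a functional surface (:func:`fit_ols`,
:func:`agreement_table`) and a model/results pair
(:class:`MethodAgreement` / :class:`AgreementResults`) whose
``summary()`` renders the familiar table layout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import SPECIES

ALPHA = 0.05

#: (predictor method, response measure) in the published row order:
#: per species, guard->loss, camera->loss, guard->events, camera->events.
FIT_GRID = [
    ("guard", "items_per_day"),
    ("camera", "items_per_day"),
    ("guard", "events_per_day"),
    ("camera", "events_per_day"),
]

_PREDICTOR_LABEL = {
    "guard": "Guard recorded crop-foraging events",
    "camera": "Camera recorded crop-foraging events",
}
_RESPONSE_LABEL = {
    "items_per_day": "Researcher recorded crop loss",
    "events_per_day": "Researcher recorded crop-foraging events",
}


@dataclass(frozen=True)
class RegressionFit:
    """Summary of one simple OLS fit y = intercept + slope * x."""

    predictor_label: str
    response_label: str
    species: str
    n: int
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    residual_se: float
    f_stat: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def __post_init__(self) -> None:
        assert -1e-12 <= self.r2 <= 1 + 1e-12
        assert self.adj_r2 <= self.r2 + 1e-12
        assert self.residual_se >= 0
        if self.r2 < 1 - 1e-12:
            expected_f = (self.n - 2) * self.r2 / (1.0 - self.r2)
            assert abs(self.f_stat - expected_f) <= 1e-8 * max(1.0, expected_f)


def fit_ols(x: np.ndarray, y: np.ndarray, **labels: str) -> RegressionFit:
    """Simple linear regression of y on x with the summary columns used here.

    adj R² = 1 − (1−R²)(n−1)/(n−2); residual SE = sqrt(SSE/(n−2));
    F on (1, n−2) df with its upper-tail p (equivalent to the slope
    t-test).  Requires n >= 3 and a non-constant predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("predictor has no variance")
    model = sm.OLS(y, sm.add_constant(x))
    res = model.fit()
    r2 = float(res.rsquared)
    sse = float(res.ssr)
    return RegressionFit(
        predictor_label=labels.get("predictor_label", "x"),
        response_label=labels.get("response_label", "y"),
        species=labels.get("species", ""),
        n=n,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=r2,
        adj_r2=float(res.rsquared_adj),
        residual_se=float(np.sqrt(sse / (n - 2))),
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
    )


def _series(measures: pd.DataFrame, method: str, measure: str, species: str) -> pd.Series:
    sel = measures[
        (measures["method"] == method)
        & (measures["measure"] == measure)
        & (measures["species"] == species)
    ]
    if sel.empty:
        raise ValueError(f"missing series: {method}/{measure}/{species}")
    return sel.set_index("period_index")["value"]


def agreement_table(measures: pd.DataFrame) -> list[RegressionFit]:
    """The eight agreement fits, in the published row order.

    Predictors are guard and camera period-mean event counts; responses
    are researcher period-mean crop loss and event counts; both species.
    Raises naming the series if any required (method, measure, species)
    combination is absent from ``measures``.
    """
    fits = []
    for species in SPECIES:  # baboon rows first, then vervet
        for predictor_method, response_measure in FIT_GRID:
            x = _series(measures, predictor_method, "events_per_day", species)
            y = _series(measures, "researcher", response_measure, species)
            common = x.index.intersection(y.index)
            fits.append(
                fit_ols(
                    x.loc[common].to_numpy(),
                    y.loc[common].to_numpy(),
                    predictor_label=_PREDICTOR_LABEL[predictor_method],
                    response_label=_RESPONSE_LABEL[response_measure],
                    species=species,
                )
            )
    return fits


def fits_to_frame(fits: list[RegressionFit]) -> pd.DataFrame:
    frame = pd.DataFrame([asdict(f) for f in fits])
    frame["significant"] = [f.significant for f in fits]
    return frame


class MethodAgreement:
    """Agreement model over a PeriodMeasure table.

    Parameters
    ----------
    measures : DataFrame
        Output of the period aggregation stage: columns period_index,
        species, method, measure, value, n_matched_days.
    """

    def __init__(self, measures: pd.DataFrame):
        required = {"period_index", "species", "method", "measure", "value"}
        missing = required - set(measures.columns)
        if missing:
            raise ValueError(f"measures table missing columns {sorted(missing)}")
        self.measures = measures

    def fit(self) -> "AgreementResults":
        return AgreementResults(self, agreement_table(self.measures))


class AgreementResults:
    """Fitted agreement regressions with a rendered summary table."""

    def __init__(self, model: MethodAgreement, fits: list[RegressionFit]):
        self.model = model
        self.fits = fits

    def to_frame(self) -> pd.DataFrame:
        return fits_to_frame(self.fits)

    def summary(self) -> str:
        """Human-readable table mirroring the standard layout.

        Note: the eight regressions are simultaneous tests at alpha=.05
        with no multiple-testing correction.
        """
        header = (
            f"{'Predictor':<38}{'Response':<42}{'Species':<9}"
            f"{'Adj. R2':>8}{'Resid. SE':>11}{'F':>8}{'p':>8}"
        )
        lines = [header, "-" * len(header)]
        for f in self.fits:
            p = "<.001" if f.p_value < 0.001 else f"{f.p_value:.3f}".lstrip("0")
            star = "*" if f.significant else ""
            lines.append(
                f"{f.predictor_label:<38}{f.response_label:<42}{f.species.title() + 's':<9}"
                f"{f.adj_r2:>8.2f}{f.residual_se:>11.2f}{f.f_stat:>8.2f}{p + star:>8}"
            )
        lines.append("* p < .05 (8 simultaneous tests, uncorrected)")
        return "\n".join(lines)
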