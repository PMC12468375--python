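"""Dose-response synergy scoring under four reference models.

A drug pair is measured on a factorial dose grid including zero doses; the
response matrix holds % inhibition (0 = untreated, 100 = full effect). Each
reference model defines the expected combination response in the absence of
interaction, and the synergy score is the unweighted mean of observed minus
expected over all positive-dose cells:

  HSA    expected = max(y_a, y_b)                      (best single agent)
  Bliss  expected = y_a + y_b - y_a*y_b/100            (probabilistic independence)
  Loewe  expected y solves x_a/D_a(y) + x_b/D_b(y) = 1 (dose equivalence;
         D inverts the fitted monotherapy Hill curve)
  ZIP    deviation of the Hill-fitted response surface from the
         independence expectation on fitted margins (potency shift model)

Scores above +5 are classed moderate synergy and above +10 strong synergy
(strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseSurface",
    "HillFit",
    "SynergySummary",
    "fit_hill",
    "bliss_score",
    "hsa_score",
    "loewe_score",
    "zip_score",
    "score_surface",
    "classify",
    "classify_and_rank",
]

MODERATE_THRESHOLD = 5.0
STRONG_THRESHOLD = 10.0


@dataclass
class DoseResponseSurface:
    """Monotherapy plus combination responses on a dose grid.

    ``conc_r``/``conc_c`` are strictly increasing and include 0; ``response``
    is % inhibition with shape (len(conc_r), len(conc_c)); cell (0, 0) is the
    untreated control.
    """

    drug_row: str
    drug_col: str
    conc_r: np.ndarray
    conc_c: np.ndarray
    response: np.ndarray
    block_id: str = ""

    def __post_init__(self) -> None:
        self.conc_r = np.asarray(self.conc_r, dtype=float)
        self.conc_c = np.asarray(self.conc_c, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        for conc in (self.conc_r, self.conc_c):
            if conc.size == 0:
                raise ValueError("empty dose grid")
            if conc[0] != 0:
                raise ValueError("dose grids must include 0 as the first point")
            if np.any(conc < 0):
                raise ValueError("negative doses")
            if np.any(np.diff(conc) <= 0):
                raise ValueError("dose grids must be strictly increasing")
        if self.response.shape != (self.conc_r.size, self.conc_c.size):
            raise ValueError("response shape does not match the dose grid")

    @property
    def pair_id(self) -> str:
        return f"{self.drug_row}+{self.drug_col}"

    def transpose(self) -> "DoseResponseSurface":
        return DoseResponseSurface(
            drug_row=self.drug_col, drug_col=self.drug_row,
            conc_r=self.conc_c.copy(), conc_c=self.conc_r.copy(),
            response=self.response.T.copy(), block_id=self.block_id,
        )


@dataclass
class HillFit:
    """Four-parameter log-logistic fit y = y_min + (y_max-y_min)/(1+(ec50/x)^slope)."""

    y_min: float
    y_max: float
    ec50: float
    slope: float
    converged: bool
    rmse: float
    # monotone interpolation fallback when the fit did not converge
    _doses: np.ndarray | None = field(default=None, repr=False)
    _responses: np.ndarray | None = field(default=None, repr=False)

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if not self.converged and self._doses is not None:
            return np.interp(x, self._doses, self._responses)
        with np.errstate(divide="ignore", over="ignore"):
            ratio = np.where(x > 0, (self.ec50 / np.maximum(x, 1e-300)) ** self.slope, np.inf)
        return self.y_min + (self.y_max - self.y_min) / (1.0 + ratio)

    def invert(self, y: float) -> float:
        """Dose producing effect y; +inf above y_max, 0 below y_min."""
        if self.y_max == self.y_min:
            raise ValueError("flat fit is not invertible")
        if y >= self.y_max:
            return np.inf
        if y <= self.y_min:
            return 0.0
        frac = (y - self.y_min) / (self.y_max - y)
        return float(self.ec50 * frac ** (1.0 / self.slope))


def _hill(x: np.ndarray, y_min: float, y_max: float, ec50: float, slope: float) -> np.ndarray:
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (ec50 / np.maximum(x, 1e-300)) ** slope, np.inf)
    return y_min + (y_max - y_min) / (1.0 + ratio)


def fit_hill(doses: np.ndarray, responses: np.ndarray, min_points: int = 4) -> HillFit:
    """Least-squares Hill fit with multi-start on the slope.

    Requires at least ``min_points`` dose points. Degenerate (flat) data
    returns a flat fit with ``converged=False``; a fit that fails to improve
    on interpolation noise falls back to monotone linear interpolation.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.size != responses.size:
        raise ValueError("doses and responses must align")
    if doses.size < min_points:
        raise ValueError(f"need at least {min_points} dose points")

    order = np.argsort(doses)
    doses, responses = doses[order], responses[order]
    spread = responses.max() - responses.min()
    if spread < 1e-9:
        flat = float(responses.mean())
        return HillFit(flat, flat, 1.0, 1.0, False, 0.0, doses, responses)

    positive = doses[doses > 0]
    ec50_init = float(np.exp(np.mean(np.log(positive)))) if positive.size else 1.0
    y_min_init = float(responses[0])
    y_max_init = float(responses.max())

    def resid(params: np.ndarray) -> np.ndarray:
        return _hill(doses, *params) - responses

    best = None
    for slope0 in (0.5, 1.0, 2.0, 4.0):
        x0 = np.array([y_min_init, y_max_init, ec50_init, slope0])
        try:
            sol = least_squares(
                resid, x0,
                bounds=([-200.0, -200.0, 1e-12, 0.05], [300.0, 300.0, 1e12, 20.0]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except Exception:  # pragma: no cover - scipy failures on pathological input
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return HillFit(y_min_init, y_max_init, ec50_init, 1.0, False, float("nan"), doses, responses)

    y_min, y_max, ec50, slope = best.x
    rmse = float(np.sqrt(2.0 * best.cost / doses.size))
    if y_min > y_max:  # keep the min <= max convention (falling curves not expected here)
        y_min, y_max = y_max, y_min
    return HillFit(float(y_min), float(y_max), float(ec50), float(slope), True, rmse)


def _check_scale(surface: DoseResponseSurface) -> np.ndarray:
    resp = surface.response
    if resp.min() < -10.0 or resp.max() > 110.0:
        logger.warning(
            "responses outside [-10, 110] on %s; clipping to [0, 100]", surface.pair_id
        )
        resp = np.clip(resp, 0.0, 100.0)
    return resp


def bliss_score(surface: DoseResponseSurface) -> float:
    """Mean deviation from probabilistic independence over positive-dose cells."""
    resp = _check_scale(surface)
    y_a = resp[1:, 0][:, None]   # monotherapy margin, row drug
    y_b = resp[0, 1:][None, :]   # monotherapy margin, column drug
    expected = y_a + y_b - y_a * y_b / 100.0
    return float(np.mean(resp[1:, 1:] - expected))


def hsa_score(surface: DoseResponseSurface) -> float:
    """Mean deviation from the highest single agent over positive-dose cells."""
    resp = _check_scale(surface)
    y_a = resp[1:, 0][:, None]
    y_b = resp[0, 1:][None, :]
    expected = np.maximum(y_a, y_b)
    return float(np.mean(resp[1:, 1:] - expected))


def _loewe_expected(y_a_fit: HillFit, y_b_fit: HillFit, x_a: float, x_b: float, tol: float = 1e-9) -> float:
    """Solve the isobole x_a/D_a(y) + x_b/D_b(y) = 1 for y by bisection."""
    lo = max(y_a_fit.y_min, y_b_fit.y_min)
    hi = min(y_a_fit.y_max, y_b_fit.y_max)
    if hi <= lo:
        raise ValueError("monotherapy effect ranges do not overlap")

    def isobole(y: float) -> float:
        total = 0.0
        for x, fit in ((x_a, y_a_fit), (x_b, y_b_fit)):
            if x > 0:
                d = fit.invert(y)
                if d == 0:
                    return np.inf
                total += x / d
        return total - 1.0

    eps = (hi - lo) * 1e-12
    y_lo, y_hi = lo + eps, hi - eps
    if isobole(y_hi) > 0:
        # doses exceed what is needed for the joint maximal effect: score
        # against the asymptotic expectation
        return y_hi
    if isobole(y_lo) < 0:
        return y_lo
    while y_hi - y_lo > tol:
        mid = 0.5 * (y_lo + y_hi)
        if isobole(mid) > 0:
            y_lo = mid
        else:
            y_hi = mid
    return 0.5 * (y_lo + y_hi)


def loewe_score(surface: DoseResponseSurface) -> float:
    """Mean deviation from Loewe (dose-equivalence) additivity.

    Monotherapy margins are Hill-fitted and inverted; cells where the
    isobole has no solution inside the joint effect range are scored
    against the nearest achievable effect (flagged in the log).
    """
    resp = _check_scale(surface)
    fit_a = fit_hill(surface.conc_r, resp[:, 0])
    fit_b = fit_hill(surface.conc_c, resp[0, :])
    if not fit_a.converged or not fit_b.converged:
        raise ValueError("monotherapy Hill fit did not converge; Loewe needs invertible margins")
    deviations = []
    for i, x_a in enumerate(surface.conc_r[1:], start=1):
        for j, x_b in enumerate(surface.conc_c[1:], start=1):
            expected = _loewe_expected(fit_a, fit_b, float(x_a), float(x_b))
            deviations.append(resp[i, j] - expected)
    return float(np.mean(deviations))


def zip_score(surface: DoseResponseSurface) -> float:
    """Mean deviation of the Hill-fitted surface from zero interaction.

    Hill curves are fitted along each row (varying the row drug at a fixed
    column dose) and each column, on the positive doses; the fitted
    combination response (average of the two directional fits) is compared
    with the independence expectation computed from the fitted monotherapy
    margins. Falls back to the raw-margin Bliss-style deviation, with a
    logged "degraded" flag, when the positive grid is too small to fit.
    """
    resp = _check_scale(surface)
    pos_r = surface.conc_r[1:]
    pos_c = surface.conc_c[1:]
    if pos_r.size < 4 or pos_c.size < 4:
        logger.warning("grid too small for ZIP fits on %s; degraded raw-margin delta", surface.pair_id)
        return bliss_score(surface)

    margin_a = fit_hill(surface.conc_r, resp[:, 0])
    margin_b = fit_hill(surface.conc_c, resp[0, :])
    y_a = np.asarray(margin_a.predict(pos_r), dtype=float)[:, None]
    y_b = np.asarray(margin_b.predict(pos_c), dtype=float)[None, :]
    expected = y_a + y_b - y_a * y_b / 100.0

    fitted_cols = np.empty((pos_r.size, pos_c.size))
    for j in range(pos_c.size):
        fitted_cols[:, j] = fit_hill(pos_r, resp[1:, j + 1]).predict(pos_r)
    fitted_rows = np.empty((pos_r.size, pos_c.size))
    for i in range(pos_r.size):
        fitted_rows[i, :] = fit_hill(pos_c, resp[i + 1, 1:]).predict(pos_c)
    fitted = 0.5 * (fitted_cols + fitted_rows)
    return float(np.mean(fitted - expected))


def classify(score: float, thresholds: tuple[float, float] = (MODERATE_THRESHOLD, STRONG_THRESHOLD)) -> str:
    """Strong iff score > +10, moderate iff > +5 (strict), else none."""
    moderate, strong = thresholds
    if score > strong:
        return "strong"
    if score > moderate:
        return "moderate"
    return "none"


@dataclass
class SynergySummary:
    """All four model scores, with classifications, for one drug pair."""

    pair_id: str
    zip_score: float
    loewe_score: float
    hsa_score: float
    bliss_score: float

    def classification(self, model: str) -> str:
        return classify(getattr(self, f"{model}_score"))

    def as_dict(self) -> dict[str, object]:
        row: dict[str, object] = {"pair_id": self.pair_id}
        for model in ("zip", "loewe", "hsa", "bliss"):
            row[model] = getattr(self, f"{model}_score")
            row[f"{model}_class"] = self.classification(model)
        return row


def score_surface(surface: DoseResponseSurface) -> SynergySummary:
    """Compute ZIP, Loewe, HSA and Bliss scores for one surface."""
    return SynergySummary(
        pair_id=surface.pair_id,
        zip_score=zip_score(surface),
        loewe_score=loewe_score(surface),
        hsa_score=hsa_score(surface),
        bliss_score=bliss_score(surface),
    )


def classify_and_rank(
    summaries: list[SynergySummary],
    thresholds: tuple[float, float] = (MODERATE_THRESHOLD, STRONG_THRESHOLD),
    top_n: int = 20,
) -> dict[str, object]:
    """Per-model top synergy lists, their union, and the all-model intersection.

    A pair counts as synergistic under a model when its score strictly
    exceeds the moderate threshold. Returns a dict with per-model DataFrames
    (``top``), the union annotated with which models fired, and the list of
    pairs synergistic under all four models.
    """
    moderate, _ = thresholds
    models = ("zip", "loewe", "hsa", "bliss")
    table = pd.DataFrame([s.as_dict() for s in summaries])
    if table.empty:
        return {"top": {m: table for m in models}, "union": table, "intersection": []}

    top: dict[str, pd.DataFrame] = {}
    fired: dict[str, set[str]] = {}
    for model in models:
        hits = table[table[model] > moderate].sort_values(
            [model, "pair_id"], ascending=[False, True], kind="mergesort"
        )
        top[model] = hits.head(top_n).reset_index(drop=True)
        fired[model] = set(hits["pair_id"])

    union_ids = sorted(set().union(*fired.values()))
    union = table[table["pair_id"].isin(union_ids)].copy()
    union["models_fired"] = union["pair_id"].map(
        lambda p: ",".join(m for m in models if p in fired[m])
    )
    union = union.sort_values("pair_id", kind="mergesort").reset_index(drop=True)
    intersection = sorted(set.intersection(*(fired[m] for m in models)))
    return {"top": top, "union": union, "intersection": intersection}
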