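"""Stent-expansion outcome metrics.

The metric cascade goes: pointwise lumen gain alpha(u) = post - pre area;
lesion-averaged relative lumen gain Lambda of a defect model over its intact
baseline; first-order influence coefficients Delta_l, Delta_w of Lambda with
respect to the defect's normalized length and width (averaged finite
differences over the 2x2 design); the Euclidean aggregate Gamma per
sub-model; and the per-arc benefit score mu combining the three sub-models.

Two printed-table conventions are deliberately exposed: Lambda in mm^2
("absolute") or as a percentage of the intact baseline's mean gain
("percent_of_baseline", the default, matching how the reference Lambda table
is stated in %); and the Gamma/mu aggregation either as the literal mean
("as_printed_formula") or as the undivided sum ("as_printed_numbers", the
default, which is the only convention consistent with the published score
values 144/192).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LumenProfile",
    "LambdaTable",
    "InfluenceSummary",
    "BenefitScores",
    "lumen_gain",
    "relative_lumen_gain",
    "influence_coefficients",
    "gamma",
    "mu",
    "round_half_away",
    "paper_lambda_table",
    "reproduce_paper_summary",
    "PaperSummary",
]

LEVELS = (Fraction(1, 3), Fraction(2, 3))


# ---------------------------------------------------------------------------
# profiles and the pointwise/averaged gains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LumenProfile:
    """Pre/post-stent lumen-area profiles on a shared normalized axial grid."""

    u: np.ndarray
    area_pre: np.ndarray
    area_post: np.ndarray
    lesion_window: tuple[float, float]

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        pre = np.asarray(self.area_pre, dtype=float)
        post = np.asarray(self.area_post, dtype=float)
        if not (u.shape == pre.shape == post.shape) or u.ndim != 1 or u.size < 3:
            raise ValueError("u, area_pre, area_post must be equal-length 1D arrays")
        if not np.all(np.diff(u) > 0):
            raise ValueError("axial grid must be strictly increasing")
        if np.any(pre <= 0) or np.any(post <= 0):
            raise ValueError("lumen areas must be positive")
        lo, hi = self.lesion_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("lesion window must be a nonempty subinterval of [0, 1]")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "area_pre", pre)
        object.__setattr__(self, "area_post", post)

    def window_mask(self, window: tuple[float, float] | None = None) -> np.ndarray:
        lo, hi = window if window is not None else self.lesion_window
        mask = (self.u >= lo - 1e-12) & (self.u <= hi + 1e-12)
        if not mask.any():
            raise ValueError("no grid points fall inside the lesion window")
        return mask


def lumen_gain(profile: LumenProfile) -> np.ndarray:
    """Pointwise lumen gain alpha(u) = A_post(u) - A_pre(u), mm^2."""
    return profile.area_post - profile.area_pre


def relative_lumen_gain(
    alpha: np.ndarray,
    alpha_baseline: np.ndarray,
    u: np.ndarray,
    window: tuple[float, float],
    mode: str = "percent_of_baseline",
) -> float:
    """Lesion-averaged relative lumen gain Lambda.

    ``mode='absolute'`` returns mean over the window of (alpha - alpha_bar)
    in mm^2; ``'percent_of_baseline'`` (default) normalizes by the baseline's
    mean gain over the same window and returns a percentage.
    """
    alpha = np.asarray(alpha, dtype=float)
    alpha_baseline = np.asarray(alpha_baseline, dtype=float)
    u = np.asarray(u, dtype=float)
    if alpha.shape != alpha_baseline.shape or alpha.shape != u.shape:
        raise ValueError("alpha, baseline and grid must share one shape")
    lo, hi = window
    mask = (u >= lo - 1e-12) & (u <= hi + 1e-12)
    if not mask.any():
        raise ValueError("empty lesion window")
    excess = float(np.mean(alpha[mask] - alpha_baseline[mask]))
    if mode == "absolute":
        return excess
    if mode == "percent_of_baseline":
        base = float(np.mean(alpha_baseline[mask]))
        if abs(base) < 1e-300:
            raise ZeroDivisionError("baseline mean gain is zero; percent mode undefined")
        return 100.0 * excess / base
    raise ValueError(f"unknown mode {mode!r}")


def relative_lumen_gain_profiles(
    profile: LumenProfile,
    baseline: LumenProfile,
    mode: str = "percent_of_baseline",
) -> float:
    """Convenience wrapper computing Lambda from two profiles on one grid."""
    if profile.u.shape != baseline.u.shape or not np.allclose(profile.u, baseline.u):
        raise ValueError("profiles must share the axial grid")
    return relative_lumen_gain(
        lumen_gain(profile), lumen_gain(baseline), profile.u, profile.lesion_window, mode
    )


# ---------------------------------------------------------------------------
# the Lambda table and its sensitivity summary
# ---------------------------------------------------------------------------

class LambdaTable:
    """Relative-lumen-gain records keyed by (arc angle, sub-model, l, w)."""

    COLUMNS = ("arc_deg", "submodel", "l", "w", "lambda_pct")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"Lambda table missing columns {sorted(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        frame["arc_deg"] = frame["arc_deg"].astype(float)
        for col in ("l", "w"):
            frame[col] = [float(Fraction(str(v))) for v in frame[col]]
        frame["lambda_pct"] = frame["lambda_pct"].astype(float)
        keys = list(zip(frame.arc_deg, frame.submodel, frame.l.round(9), frame.w.round(9)))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (arc, submodel, l, w) keys")
        bad = frame[(frame.submodel == "through") & (abs(frame.l - 1.0) > 1e-9)]
        if len(bad):
            raise ValueError("through records must have l = 1")
        self.frame = frame

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "LambdaTable":
        return cls(pd.DataFrame(list(records)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LambdaTable":
        return cls(pd.read_csv(path, dtype={"l": str, "w": str}))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def get(self, arc: float, submodel: str, l: float, w: float) -> float:
        f = self.frame
        m = (
            (f.arc_deg == float(arc))
            & (f.submodel == submodel)
            & (np.abs(f.l - float(l)) < 1e-9)
            & (np.abs(f.w - float(w)) < 1e-9)
        )
        hit = f[m]
        if len(hit) != 1:
            raise KeyError(
                f"Lambda record missing for (arc={arc}, submodel={submodel!r}, l={l}, w={w})"
            )
        return float(hit.lambda_pct.iloc[0])

    @property
    def arcs(self) -> list[float]:
        return sorted(self.frame.arc_deg.unique())


def paper_lambda_table() -> LambdaTable:
    """The embedded reference Lambda table (all 20 defect models, percent)."""
    with resources.files("lesionlab.data").joinpath("lambda_table.csv").open() as fh:
        return LambdaTable(pd.read_csv(fh, dtype={"l": str, "w": str}))


@dataclass(frozen=True)
class InfluenceSummary:
    """First-order influence coefficients per (arc, sub-model).

    ``delta_l``/``delta_w`` map (arc, submodel) to the averaged finite
    difference of Lambda with respect to l and w; the through sub-model
    carries a single width coefficient in ``delta_w``.
    """

    delta_l: dict[tuple[float, str], float]
    delta_w: dict[tuple[float, str], float]

    def rounded(self, decimals: int = 0) -> "InfluenceSummary":
        r = lambda d: {k: round_half_away(v, decimals) for k, v in d.items()}
        return InfluenceSummary(r(self.delta_l), r(self.delta_w))

    def cross_arc_average(self, which: str, submodel: str) -> float:
        d = self.delta_l if which == "l" else self.delta_w
        vals = [v for (arc, sm), v in sorted(d.items()) if sm == submodel]
        if not vals:
            raise KeyError(f"no {which}-coefficients for sub-model {submodel!r}")
        return float(np.mean(vals))


def _finite_difference(table: LambdaTable, arc: float, sub: str, vary: str) -> float:
    lo, hi = (float(x) for x in LEVELS)
    step = hi - lo
    diffs = []
    for other in (lo, hi):
        if vary == "l":
            d = table.get(arc, sub, hi, other) - table.get(arc, sub, lo, other)
        else:
            d = table.get(arc, sub, other, hi) - table.get(arc, sub, other, lo)
        diffs.append(d / step)
    return float(np.mean(diffs))


def influence_coefficients(table: LambdaTable) -> InfluenceSummary:
    """Averaged finite-difference sensitivities of Lambda over the design.

    Sided and centered sub-models get Delta_l and Delta_w (each the mean of
    the two one-parameter finite differences at the other parameter's two
    levels); the through sub-model gets the single width coefficient
    (Lambda(w=2/3) - Lambda(w=1/3)) / (1/3).
    """
    dl: dict[tuple[float, str], float] = {}
    dw: dict[tuple[float, str], float] = {}
    lo, hi = (float(x) for x in LEVELS)
    for arc in table.arcs:
        present = set(table.frame[table.frame.arc_deg == arc].submodel)
        for sub in ("sided", "centered"):
            if sub in present:
                dl[(arc, sub)] = _finite_difference(table, arc, sub, "l")
                dw[(arc, sub)] = _finite_difference(table, arc, sub, "w")
        if "through" in present:
            d = table.get(arc, "through", 1.0, hi) - table.get(arc, "through", 1.0, lo)
            dw[(arc, "through")] = d / (hi - lo)
    return InfluenceSummary(delta_l=dl, delta_w=dw)


# ---------------------------------------------------------------------------
# scalar aggregates
# ---------------------------------------------------------------------------

def gamma(delta_l: float | None = None, delta_w: float | None = None) -> float:
    """Euclidean norm of the available influence coefficients.

    With both coefficients: sqrt(Delta_l^2 + Delta_w^2); with a single one
    (the through sub-model): its absolute value.
    """
    vals = [v for v in (delta_l, delta_w) if v is not None]
    if not vals:
        raise ValueError("at least one influence coefficient is required")
    return float(math.hypot(*vals))


def mu(gammas: Sequence[float], convention: str = "as_printed_numbers") -> float:
    """Per-arc benefit score combining the sub-model aggregates.

    ``'as_printed_numbers'`` (default) sums the Gamma values — the convention
    consistent with the published scores; ``'as_printed_formula'`` takes the
    literal mean.
    """
    gammas = [float(g) for g in gammas]
    if any(g < 0 for g in gammas):
        raise ValueError("Gamma values must be nonnegative")
    total = sum(gammas)
    if convention == "as_printed_numbers":
        return total
    if convention == "as_printed_formula":
        return total / len(gammas)
    raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class BenefitScores:
    """Gamma per sub-model and the combined score, for one arc angle."""

    arc_deg: float
    gamma_sided: float
    gamma_centered: float
    gamma_through: float
    convention: str
    mu: float


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (display rounding of the printed tables)."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5), x) / q


# ---------------------------------------------------------------------------
# full published-summary reproduction
# ---------------------------------------------------------------------------

@dataclass
class PaperSummary:
    """Everything derivable from the Lambda table, full precision + rounded.

    The printed summary tables round each Delta to the nearest integer before
    averaging across arcs and before forming Gamma; both the rounded pipeline
    (matching the printed numbers) and the unrounded one are reported.
    """

    influence: InfluenceSummary
    influence_rounded: InfluenceSummary
    cross_arc_averages: dict[str, float]
    through_average: float
    gamma_rounded: dict[tuple[float, str], float]
    gamma_unrounded: dict[tuple[float, str], float]
    sided_aggregate: float
    centered_aggregate: float
    sided_aggregate_unrounded: float
    centered_aggregate_unrounded: float
    mu_scores: dict[float, float]
    mu_scores_rounded: dict[float, float]
    convention: str
    length_dominates_width: bool
    mean_length_influence: float
    mean_width_influence: float

    def to_dict(self) -> dict:
        key = lambda k: f"arc{int(k[0])}_{k[1]}"
        return {
            "delta_l": {key(k): v for k, v in self.influence.delta_l.items()},
            "delta_w": {key(k): v for k, v in self.influence.delta_w.items()},
            "delta_l_rounded": {key(k): v for k, v in self.influence_rounded.delta_l.items()},
            "delta_w_rounded": {key(k): v for k, v in self.influence_rounded.delta_w.items()},
            "cross_arc_averages": self.cross_arc_averages,
            "through_average": self.through_average,
            "gamma_rounded": {key(k): v for k, v in self.gamma_rounded.items()},
            "gamma_unrounded": {key(k): v for k, v in self.gamma_unrounded.items()},
            "sided_aggregate": self.sided_aggregate,
            "centered_aggregate": self.centered_aggregate,
            "sided_aggregate_unrounded": self.sided_aggregate_unrounded,
            "centered_aggregate_unrounded": self.centered_aggregate_unrounded,
            "mu": {f"mu_{int(a)}": v for a, v in self.mu_scores.items()},
            "mu_rounded": {f"mu_{int(a)}": v for a, v in self.mu_scores_rounded.items()},
            "convention": self.convention,
            "length_dominates_width": self.length_dominates_width,
            "mean_length_influence": self.mean_length_influence,
            "mean_width_influence": self.mean_width_influence,
        }

    def delta_table(self) -> pd.DataFrame:
        """Long-format Delta table with full-precision and rounded columns."""
        rows = []
        for (arc, sub), v in sorted(self.influence.delta_l.items()):
            rows.append((arc, sub, "l", v, self.influence_rounded.delta_l[(arc, sub)]))
        for (arc, sub), v in sorted(self.influence.delta_w.items()):
            rows.append((arc, sub, "w", v, self.influence_rounded.delta_w[(arc, sub)]))
        return pd.DataFrame(rows, columns=["arc_deg", "submodel", "parameter", "delta", "delta_rounded"])


def reproduce_paper_summary(
    table: LambdaTable | None = None,
    convention: str = "as_printed_numbers",
) -> PaperSummary:
    """Run the full metric cascade Lambda -> Delta -> Gamma -> mu.

    Uses the embedded reference Lambda table by default.  Display rounding is
    half-away-from-zero to the printed precision; rounded Delta values feed
    the cross-arc averages and the Gamma/mu aggregates, mirroring how the
    printed summary tables chain their own displayed numbers, while the
    unrounded cascade is carried alongside.
    """
    table = table if table is not None else paper_lambda_table()
    inf = influence_coefficients(table)
    infr = inf.rounded(0)
    arcs = table.arcs

    cross = {
        "delta_l_sided": infr.cross_arc_average("l", "sided"),
        "delta_w_sided": infr.cross_arc_average("w", "sided"),
        "delta_l_centered": infr.cross_arc_average("l", "centered"),
        "delta_w_centered": infr.cross_arc_average("w", "centered"),
    }
    through_avg = infr.cross_arc_average("w", "through")

    g_r: dict[tuple[float, str], float] = {}
    g_u: dict[tuple[float, str], float] = {}
    for arc in arcs:
        for sub in ("sided", "centered"):
            g_r[(arc, sub)] = gamma(infr.delta_l[(arc, sub)], infr.delta_w[(arc, sub)])
            g_u[(arc, sub)] = gamma(inf.delta_l[(arc, sub)], inf.delta_w[(arc, sub)])
        g_r[(arc, "through")] = gamma(delta_w=infr.delta_w[(arc, "through")])
        g_u[(arc, "through")] = gamma(delta_w=inf.delta_w[(arc, "through")])

    def aggregate(g: dict, sub: str) -> float:
        return mu([g[(arc, sub)] for arc in arcs], convention)

    mu_scores = {
        arc: mu([g_r[(arc, s)] for s in ("sided", "centered", "through")], convention)
        for arc in arcs
    }
    mu_rounded = {arc: round_half_away(v) for arc, v in mu_scores.items()}

    mean_l = 0.5 * (cross["delta_l_sided"] + cross["delta_l_centered"])
    mean_w = 0.5 * (cross["delta_w_sided"] + cross["delta_w_centered"])

    return PaperSummary(
        influence=inf,
        influence_rounded=infr,
        cross_arc_averages=cross,
        through_average=through_avg,
        gamma_rounded=g_r,
        gamma_unrounded=g_u,
        sided_aggregate=aggregate(g_r, "sided"),
        centered_aggregate=aggregate(g_r, "centered"),
        sided_aggregate_unrounded=aggregate(g_u, "sided"),
        centered_aggregate_unrounded=aggregate(g_u, "centered"),
        mu_scores=mu_scores,
        mu_scores_rounded=mu_rounded,
        convention=convention,
        length_dominates_width=mean_l > mean_w,
        mean_length_influence=mean_l,
        mean_width_influence=mean_w,
    )
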