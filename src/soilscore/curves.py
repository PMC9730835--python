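"""Evaluation-curve primitives mapping a measured property to a 0-1 grade.

Each soil function is graded on a unitless 0-1 scale ("distance to
target"): 1 is the optimum level above which yield no longer responds,
0.5 the level below which additional fertilization is recommended, 0 a
fully deficient soil. Four curve shapes cover the battery:

* ``two_anchor_increasing`` — piecewise linear through (x_zero, 0),
  (x_half, 0.5), (x_opt, 1); clipped outside. More is better.
* ``two_anchor_decreasing`` — the mirrored variant: less is better.
* ``optimum_window`` — trapezoid, 1 on a plateau, linear shoulders,
  0 outside (e.g. soil acidity).
* ``categorical_lookup`` — table lookup for class-valued properties
  (e.g. drought / wetness stress from the groundwater class).

The two-anchor shape anchors the curve at the two agronomically defined
levels; when a configuration omits ``x_zero`` it defaults to
``2*x_half - x_opt`` (clipped at 0 for the increasing variant), which
extends the upper segment's slope symmetrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

from .errors import ConfigurationError, EvaluationError

__all__ = [
    "CurveKind",
    "EvaluationCurveSpec",
    "eval_two_anchor",
    "eval_optimum_window",
    "eval_lookup",
]

CURVE_KINDS = (
    "two_anchor_increasing",
    "two_anchor_decreasing",
    "optimum_window",
    "categorical_lookup",
)
CurveKind = str  # one of CURVE_KINDS


def eval_two_anchor(
    x: float, x_zero: float, x_half: float, x_opt: float, *, function_id: str = "?"
) -> float:
    """Two-anchor piecewise-linear score.

    For the increasing variant (``x_zero < x_half < x_opt``) the score is
    0 at or below ``x_zero``, exactly 0.5 at ``x_half``, exactly 1 at or
    above ``x_opt``, linear on each segment. Passing the anchors in
    strictly decreasing order evaluates the mirrored variant.
    """
    if not all(math.isfinite(v) for v in (x, x_zero, x_half, x_opt)):
        raise EvaluationError(f"{function_id}: non-finite input to two-anchor curve")
    if x_zero < x_half < x_opt:
        lo, mid, hi, increasing = x_zero, x_half, x_opt, True
    elif x_zero > x_half > x_opt:
        lo, mid, hi, increasing = x_opt, x_half, x_zero, False
    else:
        raise ConfigurationError(
            f"{function_id}: two-anchor curve anchors not strictly ordered: "
            f"x_zero={x_zero}, x_half={x_half}, x_opt={x_opt}"
        )
    if x <= lo:
        s = 0.0 if increasing else 1.0
    elif x >= hi:
        s = 1.0 if increasing else 0.0
    elif x <= mid:
        frac = 0.5 * (x - lo) / (mid - lo)
        s = frac if increasing else 1.0 - frac
    else:
        frac = 0.5 + 0.5 * (x - mid) / (hi - mid)
        s = frac if increasing else 1.0 - frac
    # anchors are exact by construction; clip guards rounding at segment joins
    return min(1.0, max(0.0, s))


def eval_optimum_window(
    x: float, low0: float, low1: float, high1: float, high0: float,
    *, function_id: str = "?",
) -> float:
    """Trapezoid score: 1 on [low1, high1], 0 outside [low0, high0]."""
    if not (low0 < low1 <= high1 < high0):
        raise ConfigurationError(
            f"{function_id}: optimum window not ordered: "
            f"({low0}, {low1}, {high1}, {high0})"
        )
    if not math.isfinite(x):
        raise EvaluationError(f"{function_id}: non-finite input to window curve")
    if x <= low0 or x >= high0:
        return 0.0
    if low1 <= x <= high1:
        return 1.0
    if x < low1:
        return (x - low0) / (low1 - low0)
    return (high0 - x) / (high0 - high1)


def eval_lookup(
    key: Any, table: dict[Any, float], *,
    default: float | None = None, function_id: str = "?",
) -> float:
    """Categorical lookup; missing keys fall back to ``default`` or, in
    strict mode (``default=None``), raise an :class:`EvaluationError`."""
    if not table:
        raise ConfigurationError(f"{function_id}: empty lookup table")
    if key in table:
        return table[key]
    if default is not None:
        return default
    raise EvaluationError(f"{function_id}: no lookup entry for key {key!r}")


@dataclass
class EvaluationCurveSpec:
    """One configured curve: a kind plus its kind-specific parameters."""

    kind: CurveKind
    parameters: dict[str, Any] = field(default_factory=dict)

    def validate(self, function_id: str = "?") -> None:
        p = self.parameters
        if self.kind in ("two_anchor_increasing", "two_anchor_decreasing"):
            for name in ("x_half", "x_opt"):
                if name not in p:
                    raise ConfigurationError(
                        f"{function_id}: two-anchor curve missing parameter {name!r}"
                    )
            x_half, x_opt = float(p["x_half"]), float(p["x_opt"])
            x_zero = self._default_x_zero(x_half, x_opt)
            ordered = (
                x_zero < x_half < x_opt
                if self.kind == "two_anchor_increasing"
                else x_zero > x_half > x_opt
            )
            if not ordered:
                raise ConfigurationError(
                    f"{function_id}: anchors not strictly ordered for {self.kind}: "
                    f"x_zero={x_zero}, x_half={x_half}, x_opt={x_opt}"
                )
        elif self.kind == "optimum_window":
            try:
                low0, low1, high1, high0 = (
                    float(p[k]) for k in ("low0", "low1", "high1", "high0")
                )
            except KeyError as exc:
                raise ConfigurationError(
                    f"{function_id}: optimum window missing parameter {exc}"
                ) from None
            if not (low0 < low1 <= high1 < high0):
                raise ConfigurationError(
                    f"{function_id}: optimum window not ordered: "
                    f"({low0}, {low1}, {high1}, {high0})"
                )
        elif self.kind == "categorical_lookup":
            table = p.get("table")
            if not isinstance(table, dict) or not table:
                raise ConfigurationError(
                    f"{function_id}: categorical_lookup requires a non-empty table"
                )
            for k, v in table.items():
                if not (0.0 <= float(v) <= 1.0):
                    raise ConfigurationError(
                        f"{function_id}: lookup score for {k!r} outside [0, 1]: {v}"
                    )
            d = p.get("default")
            if d is not None and not (0.0 <= float(d) <= 1.0):
                raise ConfigurationError(
                    f"{function_id}: lookup default outside [0, 1]: {d}"
                )
        else:
            raise ConfigurationError(
                f"{function_id}: unknown curve kind {self.kind!r} "
                f"(expected one of {CURVE_KINDS})"
            )

    def _default_x_zero(self, x_half: float, x_opt: float) -> float:
        if "x_zero" in self.parameters:
            return float(self.parameters["x_zero"])
        x_zero = 2.0 * x_half - x_opt
        if self.kind == "two_anchor_increasing":
            # physical properties are non-negative; do not anchor below 0
            # unless that would break strict ordering
            x_zero = max(0.0, x_zero) if x_half > 0 else x_zero
        return x_zero

    def evaluate(self, x: Any, function_id: str = "?") -> float:
        """Apply this curve to a property value (or lookup key)."""
        p = self.parameters
        if self.kind in ("two_anchor_increasing", "two_anchor_decreasing"):
            x_half, x_opt = float(p["x_half"]), float(p["x_opt"])
            x_zero = self._default_x_zero(x_half, x_opt)
            return eval_two_anchor(
                float(x), x_zero, x_half, x_opt, function_id=function_id
            )
        if self.kind == "optimum_window":
            return eval_optimum_window(
                float(x), float(p["low0"]), float(p["low1"]),
                float(p["high1"]), float(p["high0"]), function_id=function_id,
            )
        if self.kind == "categorical_lookup":
            return eval_lookup(
                x, p["table"], default=p.get("default"), function_id=function_id
            )
        raise ConfigurationError(f"{function_id}: unknown curve kind {self.kind!r}")
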