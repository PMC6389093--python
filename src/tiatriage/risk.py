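"""Time-dependent recurrent-stroke risk curves per ABCD2 stratum.

Recurrent-stroke risk after TIA/minor stroke is front-loaded: a large
share of the 90-day risk accrues within the first days after symptom
onset.  This module represents that as a piecewise-exponential hazard per
ABCD2 risk band, fitted so the implied cumulative incidence reproduces a
set of literature anchor risks exactly.

Given anchors ``(h₁, r₁), …, (h_k, r_k)`` (cumulative risk r at horizon h
days), the cumulative hazard at h_j is ``H_j = -log(1 - r_j)`` and the
hazard on ``(h_{j-1}, h_j]`` is constant at ``(H_j - H_{j-1}) /
(h_j - h_{j-1})``; beyond the last anchor the hazard is zero.

Triage uses the *remaining* risk at elapsed time t since onset — the
conditional probability of recurrence in ``(t, h_k]`` given event-free
survival to t, ``1 - S(h_k)/S(t)`` — which is non-increasing in t: a
patient seen later has a shrinking actionable window.

The default anchors bundled here are the widely used ABCD2 validation
risks at 2, 7 and 90 days per band; they are placeholders a deployment
should replace with its preferred literature values via the anchors
config file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .scoring import RiskStratum

Anchors = list[tuple[float, float]]


class RiskModelError(ValueError):
    """Invalid anchor set (decreasing risks, risk >= 1, bad horizons)."""


# Cumulative recurrent-stroke risk at 2/7/90 days by ABCD2 band, from the
# original multi-cohort ABCD2 validation literature.  Front-loaded: most
# of the 90-day risk is present within the first week.
DEFAULT_ANCHORS: dict[RiskStratum, Anchors] = {
    RiskStratum.LOW: [(2, 0.010), (7, 0.012), (90, 0.031)],
    RiskStratum.MODERATE: [(2, 0.041), (7, 0.059), (90, 0.098)],
    RiskStratum.HIGH: [(2, 0.081), (7, 0.117), (90, 0.178)],
}


@dataclass(frozen=True)
class RiskCurve:
    """Piecewise-exponential risk curve for one ABCD2 stratum.

    ``boundaries`` are the interval edges in days, starting at 0;
    ``hazards[i]`` is the constant hazard per day on
    ``(boundaries[i], boundaries[i+1]]``.
    """

    stratum: RiskStratum
    boundaries: np.ndarray
    hazards: np.ndarray

    @property
    def max_horizon_days(self) -> float:
        return float(self.boundaries[-1])

    def cumulative_hazard(self, t_days):
        """H(t) = ∫₀^t hazard; flat beyond the last anchor horizon."""
        t = np.asarray(t_days, dtype=float)
        if np.any(t < 0):
            raise RiskModelError("t_days must be non-negative")
        exposure = np.clip(
            t[..., None] - self.boundaries[:-1], 0.0, np.diff(self.boundaries)
        )
        return exposure @ self.hazards

    def survival(self, t_days):
        """Probability of remaining recurrence-free to t."""
        return np.exp(-self.cumulative_hazard(t_days))

    def cumulative_risk(self, t_days):
        """1 - S(t): cumulative incidence of recurrence by t."""
        return -np.expm1(-self.cumulative_hazard(t_days))

    def remaining_risk(self, t_days):
        """Conditional risk of recurrence in (t, max_horizon] given
        event-free survival to t; 0 at and beyond the horizon."""
        h_t = self.cumulative_hazard(t_days)
        h_max = self.cumulative_hazard(self.max_horizon_days)
        out = -np.expm1(-(h_max - h_t))
        return float(out) if np.isscalar(t_days) else out


def fit_risk_curve(anchors: Anchors, stratum: RiskStratum) -> RiskCurve:
    """Fit a piecewise-exponential hazard reproducing every anchor exactly."""
    if not anchors:
        raise RiskModelError("at least one anchor is required")
    anchors = sorted((float(h), float(r)) for h, r in anchors)
    horizons = np.array([h for h, _ in anchors])
    risks = np.array([r for _, r in anchors])
    if horizons[0] <= 0 or np.any(np.diff(horizons) <= 0):
        raise RiskModelError("anchor horizons must be positive and strictly increasing")
    if np.any(risks < 0) or np.any(risks >= 1):
        raise RiskModelError("anchor risks must lie in [0, 1)")
    if np.any(np.diff(risks) < 0):
        raise RiskModelError("anchor risks must be non-decreasing in horizon")

    cum_hazard = -np.log1p(-risks)
    boundaries = np.concatenate([[0.0], horizons])
    hazards = np.diff(np.concatenate([[0.0], cum_hazard])) / np.diff(boundaries)
    return RiskCurve(stratum=stratum, boundaries=boundaries, hazards=hazards)


def remaining_risk(curve: RiskCurve, t_days: float) -> float:
    """Module-level convenience wrapper around RiskCurve.remaining_risk."""
    return float(curve.remaining_risk(t_days))


def default_risk_curves() -> dict[RiskStratum, RiskCurve]:
    """Curves fitted to the bundled default anchors, one per stratum."""
    return {s: fit_risk_curve(a, s) for s, a in DEFAULT_ANCHORS.items()}


def load_anchors(path: str | Path) -> dict[RiskStratum, Anchors]:
    """Read an anchors YAML file: ``{LOW: [[2, 0.01], ...], ...}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return {
            RiskStratum[name.upper()]: [(float(h), float(r)) for h, r in pairs]
            for name, pairs in raw.items()
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise RiskModelError(f"invalid anchors file {path}: {exc}") from exc


def curves_from_anchors(anchors: dict[RiskStratum, Anchors]) -> dict[RiskStratum, RiskCurve]:
    return {s: fit_risk_curve(a, s) for s, a in anchors.items()}


def write_anchor_template(path: str | Path) -> None:
    """Write the default anchors as an editable YAML template."""
    payload = {
        s.name: [[h, r] for h, r in a] for s, a in DEFAULT_ANCHORS.items()
    }
    with open(path, "w") as fh:
        fh.write(
            "# Cumulative recurrent-stroke risk anchors per ABCD2 band:\n"
            "# stratum -> list of [horizon_days, cumulative_risk].\n"
            "# Replace with your preferred literature values.\n"
        )
        yaml.safe_dump(payload, fh, sort_keys=True)
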