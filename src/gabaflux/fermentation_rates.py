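"""Specific growth and exchange rates from batch fermentation time courses.

The measured inputs of the flux pipeline are batch profiles: optical density
(OD600) and metabolite concentrations (g/l) over time.  During balanced
exponential growth X(t) = X₀·e^{μt}, a species produced or consumed at a
constant specific rate q (mmol/gDCW/h) has a concentration that is *linear in
biomass*:  dC/dt = q·X  ⇒  C = C₀ + (q/μ)·(X − X₀).  The estimator therefore

1. selects the log phase as the time window of maximal ln-OD slope,
2. fits μ as the least-squares slope of ln(OD600) vs time in that window,
3. fits each species' molar concentration against biomass concentration and
   reports q = μ · dC/dX (exact under exponential balanced growth).

Signs follow the exchange convention: consumption (falling concentration)
gives a negative rate, production a positive one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FermentationProfile",
    "RateEstimate",
    "ConditionConstraints",
    "MOLAR_MASSES",
    "DEFAULT_BIOMASS_FACTOR",
    "select_log_phase",
    "estimate_growth_rate",
    "estimate_specific_rates",
    "to_condition_constraints",
    "read_profile",
    "write_profile",
    "load_rate_table",
]

#: g/mol; overridable in every estimator call.
MOLAR_MASSES: dict[str, float] = {
    "glucose": 180.16,
    "succinate": 118.09,
    "gaba": 103.12,
    "glutamate": 147.13,
    "acetate": 60.05,
}

#: gDCW per litre per OD600 unit; the OD-to-dry-weight conversion.
DEFAULT_BIOMASS_FACTOR = 0.36

#: which way each measured species crosses the membrane in this strain
SPECIES_DIRECTIONS: dict[str, str] = {
    "glucose": "uptake",
    "succinate": "uptake",
    "gaba": "secretion",
    "glutamate": "secretion",
    "acetate": "secretion",
}


@dataclass
class FermentationProfile:
    """One batch run: times (h), OD600 and species concentrations (g/l)."""

    times: np.ndarray
    od600: np.ndarray
    concentrations: dict[str, np.ndarray]
    condition_label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        self.concentrations = {k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()}
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.od600) != len(self.times):
            raise ValueError("od600 and times length mismatch")
        if np.any(self.od600 <= 0):
            raise ValueError("od600 must be positive")
        for species, conc in self.concentrations.items():
            if len(conc) != len(self.times):
                raise ValueError(f"{species}: concentration/time length mismatch")
            if np.any(conc < 0):
                raise ValueError(f"{species}: negative concentration")

    @property
    def species(self) -> list[str]:
        return list(self.concentrations)

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        t_start, t_end = window
        return (self.times >= t_start - 1e-12) & (self.times <= t_end + 1e-12)


@dataclass
class RateEstimate:
    """μ (h⁻¹) and signed specific rates q (mmol/gDCW/h) for one window."""

    mu: float
    q: dict[str, float]
    window: tuple[float, float]
    r_squared: dict[str, float] = field(default_factory=dict)
    condition_label: str = ""


@dataclass
class ConditionConstraints:
    """The six measured quantities constraining one culture condition."""

    growth_rate: float
    rates: dict[str, tuple[float, str]]  # species -> (magnitude, direction)
    provenance: str = "estimated"
    label: str = ""

    def __post_init__(self):
        clean = {}
        for species, (magnitude, direction) in dict(self.rates).items():
            if magnitude < 0:
                raise ValueError(f"{species}: constraint magnitude must be >= 0")
            if direction not in ("uptake", "secretion"):
                raise ValueError(f"{species}: bad direction {direction!r}")
            clean[species] = (float(magnitude), direction)
        self.rates = clean

    def signed(self) -> dict[str, float]:
        return {
            species: (-magnitude if direction == "uptake" else magnitude)
            for species, (magnitude, direction) in self.rates.items()
        }

    def to_json(self, path) -> None:
        doc = {
            "label": self.label,
            "provenance": self.provenance,
            "growth_rate_per_h": self.growth_rate,
            "rates_mmol_per_gdcw_h": {
                species: {"magnitude": magnitude, "direction": direction}
                for species, (magnitude, direction) in self.rates.items()
            },
        }
        with open(path, "w") as handle:
            json.dump(doc, handle, indent=1)
            handle.write("\n")

    @classmethod
    def from_json(cls, path) -> "ConditionConstraints":
        with open(path) as handle:
            doc = json.load(handle)
        return cls(
            growth_rate=doc["growth_rate_per_h"],
            rates={
                species: (entry["magnitude"], entry["direction"])
                for species, entry in doc["rates_mmol_per_gdcw_h"].items()
            },
            provenance=doc.get("provenance", "estimated"),
            label=doc.get("label", ""),
        )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def _ln_od_slope(times: np.ndarray, od: np.ndarray) -> float:
    slope, _ = np.polyfit(times, np.log(od), 1)
    return float(slope)


def select_log_phase(profile: FermentationProfile, window_hours: float) -> tuple[float, float]:
    """Find the window of given width with the steepest ln(OD600) slope.

    Candidate windows are anchored at every sample time (plus one flush with
    the end of the profile); the returned window maximises the least-squares
    slope of ln(OD) vs time over in-window samples, ties broken toward the
    earliest start.
    """
    if window_hours <= 0:
        raise ValueError("window_hours must be positive")
    span = profile.times[-1] - profile.times[0]
    if span < window_hours - 1e-12:
        raise ValueError(
            f"profile spans {span:g} h, shorter than the requested {window_hours:g} h window"
        )
    starts = [t for t in profile.times if t + window_hours <= profile.times[-1] + 1e-12]
    tail_start = profile.times[-1] - window_hours
    if not starts or abs(starts[-1] - tail_start) > 1e-12:
        starts.append(tail_start)
    best: tuple[float, float] | None = None
    best_slope = -np.inf
    for t0 in starts:
        window = (float(t0), float(t0 + window_hours))
        mask = profile.window_mask(window)
        if mask.sum() < 3:
            continue
        slope = _ln_od_slope(profile.times[mask], profile.od600[mask])
        if slope > best_slope + 1e-12:
            best_slope = slope
            best = window
    if best is None:
        raise ValueError("no candidate window contains at least 3 samples")
    return best


def estimate_growth_rate(profile: FermentationProfile, window: tuple[float, float]) -> float:
    """μ = least-squares slope of ln(OD600) vs time within the window."""
    mask = profile.window_mask(window)
    if mask.sum() < 3:
        raise ValueError(f"window {window} contains fewer than 3 samples")
    od = profile.od600[mask]
    if np.any(od <= 0):
        raise ValueError("non-positive OD600 inside the fit window")
    return _ln_od_slope(profile.times[mask], od)


def _linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope plus R² (R²=1 for an exactly flat response)."""
    slope, intercept = np.polyfit(x, y, 1)
    predicted = slope * x + intercept
    ss_res = float(np.sum((y - predicted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot < 1e-300 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def estimate_specific_rates(
    profile: FermentationProfile,
    window: tuple[float, float],
    biomass_factor: float = DEFAULT_BIOMASS_FACTOR,
    molar_masses: Mapping[str, float] | None = None,
) -> RateEstimate:
    """Specific exchange rates q = μ · dC/dX for every profiled species.

    C is molar concentration (mmol/l), X biomass concentration
    (gDCW/l = biomass_factor · OD600).  Under exponential balanced growth the
    C-vs-X relation is exactly linear and the estimator is exact; the per-fit
    R² diagnostics flag departures.  Consumption yields q < 0.
    """
    masses = dict(MOLAR_MASSES)
    masses.update(molar_masses or {})
    mu = estimate_growth_rate(profile, window)
    mask = profile.window_mask(window)
    biomass = biomass_factor * profile.od600[mask]
    q: dict[str, float] = {}
    diagnostics: dict[str, float] = {}
    for species, conc in profile.concentrations.items():
        if species not in masses:
            raise ValueError(f"no molar mass configured for species {species!r}")
        molar = conc[mask] * 1000.0 / masses[species]
        slope, r2 = _linear_fit(biomass, molar)
        q[species] = mu * slope
        diagnostics[species] = r2
    return RateEstimate(
        mu=mu,
        q=q,
        window=(float(window[0]), float(window[1])),
        r_squared=diagnostics,
        condition_label=profile.condition_label,
    )


def to_condition_constraints(estimate: RateEstimate) -> ConditionConstraints:
    """Split signed rates into (magnitude, direction) condition constraints."""
    rates = {
        species: (abs(value), "uptake" if value < 0 else "secretion")
        for species, value in estimate.q.items()
    }
    return ConditionConstraints(
        growth_rate=estimate.mu,
        rates=rates,
        provenance="estimated",
        label=estimate.condition_label,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_profile(path, condition_label: str | None = None) -> FermentationProfile:
    """Read a profile table: columns time_h, od600, then species in g/l."""
    frame = pd.read_csv(path, sep="\t")
    required = {"time_h", "od600"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    species_cols = [c for c in frame.columns if c not in required]
    return FermentationProfile(
        times=frame["time_h"].to_numpy(),
        od600=frame["od600"].to_numpy(),
        concentrations={c: frame[c].to_numpy() for c in species_cols},
        condition_label=condition_label or "",
    )


def write_profile(profile: FermentationProfile, path) -> None:
    frame = pd.DataFrame({"time_h": profile.times, "od600": profile.od600})
    for species, conc in profile.concentrations.items():
        frame[species] = conc
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_rate_table(path) -> dict[str, ConditionConstraints]:
    """Read a measured-rate table (one row per condition) into constraints.

    Expected columns: condition, glucose, succinate, gaba, glutamate,
    acetate (all mmol/gDCW/h magnitudes) and growth_rate (h⁻¹).  Directions
    are fixed by ``SPECIES_DIRECTIONS`` (substrates uptake, products
    secretion).
    """
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, ConditionConstraints] = {}
    for _, row in frame.iterrows():
        label = str(row["condition"])
        rates = {
            species: (float(row[species]), SPECIES_DIRECTIONS[species])
            for species in SPECIES_DIRECTIONS
            if species in frame.columns
        }
        out[label] = ConditionConstraints(
            growth_rate=float(row["growth_rate"]),
            rates=rates,
            provenance="measured-table",
            label=label,
        )
    return out
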