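"""Phase maps: sweep protocol parameters x conditions, extract thresholds.

Reproduces the model's in-silico phase boundaries: the smallest theta-burst
train count at which LTP fails under LDH inhibition, the smallest 2-bAP
pairing count at which it fails, and the bath-glucose dependence of
TBS-LTP under LDH block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import pharmacology, protocols, simulate
from .params import Params, load_default_params
from .plasticity import LTP_THRESHOLD_PCT

__all__ = ["PhaseMap", "sweep", "tbs_train_axis", "stdp_pairing_axis", "glucose_axis"]


@dataclass
class PhaseMap:
    """Grid of outcomes along one protocol/condition axis."""

    axis_name: str
    values: np.ndarray
    magnitudes: np.ndarray  # % of baseline at 50-60 min
    labels: list[str]
    condition: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.axis_name: self.values,
                "magnitude_pct": self.magnitudes,
                "label": self.labels,
            }
        )

    @property
    def is_ltp(self) -> np.ndarray:
        return np.array([lab == "LTP" for lab in self.labels])

    def change_points(self) -> list[float]:
        """Axis values at which the LTP label changes (all of them)."""
        flags = self.is_ltp
        return [
            float(self.values[i + 1])
            for i in range(len(flags) - 1)
            if flags[i] != flags[i + 1]
        ]

    def failure_threshold(self) -> float | None:
        """Smallest axis value labelled non-LTP; None if LTP everywhere.

        If the outcome is non-monotone along the axis, all change points are
        preserved in :meth:`change_points`; this accessor still reports the
        smallest failing value rather than silently picking a boundary.
        """
        flags = self.is_ltp
        fail = np.where(~flags)[0]
        return float(self.values[fail[0]]) if len(fail) else None

    def largest_ltp(self) -> float | None:
        """Largest axis value still labelled LTP."""
        ok = np.where(self.is_ltp)[0]
        return float(self.values[ok[-1]]) if len(ok) else None


def sweep(
    axis_name: str,
    values: Sequence[float],
    protocol_factory: Callable[[float], protocols.StimulationProtocol],
    condition=None,
    params: Params | None = None,
) -> PhaseMap:
    """One simulation per grid point (deterministic, cached by parameters).

    ``values`` must be finite and sorted ascending.
    """
    values = np.asarray(list(values), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("axis values must be finite")
    if np.any(np.diff(values) < 0):
        raise ValueError("axis values must be sorted ascending")
    params = params or load_default_params()
    mags, labels = [], []
    for v in values:
        res = simulate.run_cached(protocol_factory(v), condition, params)
        out = res.outcome
        mags.append(out.magnitude_pct)
        labels.append(out.label)
    return PhaseMap(
        axis_name=axis_name,
        values=values,
        magnitudes=np.array(mags),
        labels=labels,
        condition=pharmacology.condition_names(condition),
    )


# -- canonical axes ---------------------------------------------------------

def tbs_train_axis(
    trains: Iterable[int] = range(1, 6), condition="oxamate", params=None
) -> PhaseMap:
    """Theta-burst train count axis (burst-number phase boundary)."""
    return sweep(
        "tbs_trains",
        list(trains),
        lambda n: protocols.tbs(int(n)),
        condition,
        params,
    )


def stdp_pairing_axis(
    pairings: Iterable[int],
    pairing_rate: float = 1.0,
    baps_per_pairing: int = 1,
    condition="oxamate",
    params=None,
    refine: bool = False,
) -> PhaseMap:
    """STDP pairing-count axis; ``refine`` bisects the LTP/no-LTP boundary
    down to single-pairing resolution."""
    vals = sorted(int(v) for v in pairings)
    pm = sweep(
        "n_pairings",
        vals,
        lambda n: protocols.stdp(int(n), pairing_rate, baps_per_pairing),
        condition,
        params,
    )
    if refine:
        thr = pm.failure_threshold()
        if thr is not None and thr > pm.values[0]:
            lo = int(pm.values[np.searchsorted(pm.values, thr) - 1])
            hi = int(thr)
            while hi - lo > 1:
                mid = (lo + hi) // 2
                res = simulate.run_cached(
                    protocols.stdp(mid, pairing_rate, baps_per_pairing),
                    condition,
                    params or load_default_params(),
                )
                if res.outcome.label == "LTP":
                    lo = mid
                else:
                    hi = mid
            dense = sorted(set(list(pm.values.astype(int)) + [lo, hi]))
            pm = sweep(
                "n_pairings",
                dense,
                lambda n: protocols.stdp(int(n), pairing_rate, baps_per_pairing),
                condition,
                params,
            )
    return pm


def glucose_axis(
    glucose_mM: Iterable[float] = (1.0, 2.5, 5.0, 10.0, 15.0, 20.0, 25.0),
    protocol: protocols.StimulationProtocol | None = None,
    condition="oxamate",
    params=None,
) -> PhaseMap:
    """Bath-glucose axis for TBS-LTP under LDH inhibition (glucose rescue)."""
    params = params or load_default_params()
    protocol = protocol or protocols.get_preset("tbs5")
    base_conds = pharmacology._as_conditions(condition)
    values = np.asarray(sorted(glucose_mM), dtype=float)
    mags, labels = [], []
    for g in values:
        glc = pharmacology.PharmacologyCondition(
            f"glucose_{g:g}",
            (pharmacology.Override("bath_glucose", "set", float(g)),),
            "bath",
        )
        res = simulate.run_cached(protocol, base_conds + [glc], params)
        out = res.outcome
        mags.append(out.magnitude_pct)
        labels.append(out.label)
    return PhaseMap(
        axis_name="bath_glucose_mM",
        values=values,
        magnitudes=np.array(mags),
        labels=labels,
        condition=pharmacology.condition_names(condition),
    )
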