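"""Declarative TBS / STDP stimulation paradigms compiled to spike trains.

TBS: nested 100 Hz bursts (4 pulses) at 5 Hz theta rhythm, 10 bursts per
train, trains repeated at 0.1 Hz; the standard "5-TBS" paradigm therefore
delivers 5 x 10 x 4 = 200 presynaptic stimulations, each of which also
evokes a postsynaptic depolarization.

STDP: repeated pre-then-post pairings at a fixed (positive) spike-timing
delay, optionally with several back-propagating action potentials (bAPs)
per pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

from .errors import EventOrderError, ScheduleError

__all__ = ["SpikeEvent", "StimulationProtocol", "tbs", "stdp", "PRESETS", "get_preset"]

_SITE_ORDER = {"presynaptic": 0, "postsynaptic": 1}


@dataclass(frozen=True, order=False)
class SpikeEvent:
    """A timed spike: presynaptic stimulation or postsynaptic bAP."""

    time: float  # s
    site: Literal["presynaptic", "postsynaptic"]
    kind: Literal["stimulation", "bAP"]

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("event time must be >= 0")

    def sort_key(self):
        # stable ordering with presynaptic before postsynaptic on ties
        return (self.time, _SITE_ORDER[self.site])


@dataclass(frozen=True)
class StimulationProtocol:
    """Declarative description of a TBS or STDP paradigm."""

    kind: Literal["TBS", "STDP"]
    # TBS fields
    n_trains: int = 5
    bursts_per_train: int = 10
    pulses_per_burst: int = 4
    intra_burst_rate: float = 100.0  # Hz
    burst_rate: float = 5.0  # Hz
    train_rate: float = 0.1  # Hz
    # STDP fields
    n_pairings: int = 50
    pairing_rate: float = 0.5  # Hz
    delta_t: float = 10.0  # ms, t_post - t_pre (> 0, LTP pairings)
    baps_per_pairing: int = 1
    intra_bap_interval: float = 10.0  # ms
    name: str = ""

    def __post_init__(self):
        counts = (
            (self.n_trains, self.bursts_per_train, self.pulses_per_burst)
            if self.kind == "TBS"
            else (self.n_pairings, self.baps_per_pairing)
        )
        if any(c < 1 for c in counts):
            raise ValueError("all protocol counts must be >= 1")
        rates = (
            (self.intra_burst_rate, self.burst_rate, self.train_rate)
            if self.kind == "TBS"
            else (self.pairing_rate,)
        )
        if any(r <= 0 for r in rates):
            raise ValueError("all protocol rates must be > 0")

    # -- closed forms --------------------------------------------------------
    @property
    def n_events(self) -> int:
        if self.kind == "TBS":
            return self.n_trains * self.bursts_per_train * self.pulses_per_burst
        return self.n_pairings * (1 + self.baps_per_pairing)

    @property
    def span(self) -> float:
        """Time of the last event (s), first event at t = 0."""
        if self.kind == "TBS":
            return (
                (self.n_trains - 1) / self.train_rate
                + (self.bursts_per_train - 1) / self.burst_rate
                + (self.pulses_per_burst - 1) / self.intra_burst_rate
            )
        return (
            (self.n_pairings - 1) / self.pairing_rate
            + self.delta_t / 1000.0
            + (self.baps_per_pairing - 1) * self.intra_bap_interval / 1000.0
        )

    def _validate_schedule(self) -> None:
        if self.kind == "TBS":
            burst_len = (self.pulses_per_burst - 1) / self.intra_burst_rate
            if self.bursts_per_train > 1 and burst_len >= 1.0 / self.burst_rate:
                raise ScheduleError("bursts overlap: burst longer than burst period")
            train_len = (self.bursts_per_train - 1) / self.burst_rate + burst_len
            if self.n_trains > 1 and train_len >= 1.0 / self.train_rate:
                raise ScheduleError("trains overlap: train longer than train period")
        else:
            pairing_len = (
                self.delta_t + (self.baps_per_pairing - 1) * self.intra_bap_interval
            ) / 1000.0
            if self.n_pairings > 1 and pairing_len >= 1.0 / self.pairing_rate:
                raise ScheduleError("pairings overlap: pairing longer than period")
            if self.delta_t <= 0:
                raise ScheduleError("only positive spike-timing delays are supported")

    # -- compilation ---------------------------------------------------------
    def compile(self) -> list[SpikeEvent]:
        """Deterministic, time-sorted event train (idempotent)."""
        self._validate_schedule()
        events: list[SpikeEvent] = []
        if self.kind == "TBS":
            for k in range(self.n_trains):
                t_train = k / self.train_rate
                for b in range(self.bursts_per_train):
                    t_burst = t_train + b / self.burst_rate
                    for s in range(self.pulses_per_burst):
                        events.append(
                            SpikeEvent(
                                t_burst + s / self.intra_burst_rate,
                                "presynaptic",
                                "stimulation",
                            )
                        )
        else:
            for k in range(self.n_pairings):
                t0 = k / self.pairing_rate
                events.append(SpikeEvent(t0, "presynaptic", "stimulation"))
                for b in range(self.baps_per_pairing):
                    events.append(
                        SpikeEvent(
                            t0
                            + self.delta_t / 1000.0
                            + b * self.intra_bap_interval / 1000.0,
                            "postsynaptic",
                            "bAP",
                        )
                    )
        events.sort(key=SpikeEvent.sort_key)
        assert len(events) == self.n_events
        return events

    def label(self) -> str:
        if self.name:
            return self.name
        if self.kind == "TBS":
            return f"tbs{self.n_trains}"
        tag = f"stdp{self.n_pairings}@{self.pairing_rate:g}Hz"
        if self.baps_per_pairing > 1:
            tag += f"x{self.baps_per_pairing}bAP"
        return tag


def events_to_frame(events: list[SpikeEvent]):
    """Two-column tabular form of an event train (time_s, site.kind)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time_s": [e.time for e in events],
            "event": [f"{e.site}.{e.kind}" for e in events],
        }
    )


def events_from_frame(df) -> list[SpikeEvent]:
    """Inverse of :func:`events_to_frame`."""
    out = []
    for t, tag in zip(df["time_s"], df["event"]):
        site, kind = tag.split(".")
        out.append(SpikeEvent(float(t), site, kind))
    out.sort(key=SpikeEvent.sort_key)
    return out


def check_sorted(events: list[SpikeEvent]) -> None:
    keys = [e.sort_key() for e in events]
    if keys != sorted(keys):
        raise EventOrderError("spike events are not time-sorted")


def tbs(n_trains: int = 5, **kw) -> StimulationProtocol:
    return StimulationProtocol(kind="TBS", n_trains=n_trains, **kw)


def stdp(
    n_pairings: int = 50,
    pairing_rate: float = 0.5,
    baps_per_pairing: int = 1,
    **kw,
) -> StimulationProtocol:
    return StimulationProtocol(
        kind="STDP",
        n_pairings=n_pairings,
        pairing_rate=pairing_rate,
        baps_per_pairing=baps_per_pairing,
        **kw,
    )


#: Named presets for every paradigm used in the study.
PRESETS: dict[str, StimulationProtocol] = {
    "tbs5": tbs(5, name="tbs5"),
    "tbs1": tbs(1, name="tbs1"),
    "stdp_50_0.5Hz": stdp(50, 0.5, 1, name="stdp_50_0.5Hz"),
    "stdp_100_1Hz": stdp(100, 1.0, 1, name="stdp_100_1Hz"),
    "stdp_50_1Hz_2bAP": stdp(50, 1.0, 2, name="stdp_50_1Hz_2bAP"),
    "stdp_25_1Hz_2bAP": stdp(25, 1.0, 2, name="stdp_25_1Hz_2bAP"),
    "stdp_25_0.5Hz_2bAP": stdp(25, 0.5, 2, name="stdp_25_0.5Hz_2bAP"),
}


def get_preset(name: str) -> StimulationProtocol:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
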