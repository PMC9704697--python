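"""Versioned parameter table for the neuro-glia metabolism + plasticity model.

Every parameter carries a value, units and a provenance tag so that the
origin of each number stays auditable:

``base``
    structural default taken from the neuron-glia metabolic modelling
    literature (reversible Michaelis-Menten transporters, saturable LDH,
    phenomenological mitochondrial ATP production).
``recalibrated``
    tuned against the model's own quantitative predictions (resting ATP under
    LDH block, Na/Ca transient amplitudes, pump ATP budgets, phase
    thresholds) or refit from synaptic-weight time courses.

The table is stored as plain YAML (``data/default_params.yaml``) and loaded
into a :class:`Params` object that behaves like a read-only attribute
namespace with copy-on-write overrides.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = ["ParamEntry", "Params", "load_default_params", "load_params"]

_VALID_PROVENANCE = {"base", "recalibrated"}


@dataclass(frozen=True)
class ParamEntry:
    """One named model parameter with units and provenance."""

    name: str
    value: float
    units: str = ""
    provenance: str = "base"

    def __post_init__(self) -> None:
        if self.provenance not in _VALID_PROVENANCE:
            raise ValueError(f"unknown provenance tag {self.provenance!r}")
        if not math.isfinite(self.value):
            raise ValueError(f"parameter {self.name!r} is not finite")


class Params:
    """Immutable mapping of parameter name -> :class:`ParamEntry`.

    Attribute access returns the float value (``p.bath_glucose``); the full
    entry (units, provenance) is available via ``p.entry(name)``.
    """

    __slots__ = ("_entries",)

    def __init__(self, entries: Mapping[str, ParamEntry]):
        object.__setattr__(self, "_entries", dict(entries))

    # -- mapping-ish surface -------------------------------------------------
    def __getattr__(self, name: str) -> float:
        try:
            return self._entries[name].value
        except KeyError:
            raise AttributeError(f"no parameter named {name!r}") from None

    def __getitem__(self, name: str) -> float:
        return self._entries[name].value

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def entry(self, name: str) -> ParamEntry:
        return self._entries[name]

    def names(self) -> list[str]:
        return sorted(self._entries)

    def to_dict(self) -> dict[str, float]:
        return {k: e.value for k, e in self._entries.items()}

    # -- derivation ----------------------------------------------------------
    def with_overrides(
        self,
        overrides: Mapping[str, float],
        provenance: str = "recalibrated",
    ) -> "Params":
        """Return a new table with ``overrides`` applied by absolute value."""
        entries = dict(self._entries)
        for name, value in overrides.items():
            if name not in entries:
                raise KeyError(f"override targets unknown parameter {name!r}")
            old = entries[name]
            entries[name] = ParamEntry(name, float(value), old.units, provenance)
        return Params(entries)

    def scaled(self, factors: Mapping[str, float]) -> "Params":
        """Return a new table with multiplicative scale factors applied."""
        return self.with_overrides(
            {k: self._entries[k].value * f for k, f in factors.items()}
        )

    def hash(self) -> str:
        """Stable hash of the numeric content (used for sweep caching)."""
        h = hashlib.sha256()
        for name in sorted(self._entries):
            h.update(name.encode())
            h.update(repr(self._entries[name].value).encode())
        return h.hexdigest()[:16]

    def diff(self, other: "Params") -> list[str]:
        """Names whose values differ between two tables."""
        return sorted(
            k
            for k in set(self._entries) | set(other._entries)
            if (k not in self._entries)
            or (k not in other._entries)
            or self._entries[k].value != other._entries[k].value
        )

    # -- I/O -----------------------------------------------------------------
    @classmethod
    def from_yaml_text(cls, text: str) -> "Params":
        raw = yaml.safe_load(text)
        entries = {}
        for name, spec in raw.items():
            if isinstance(spec, Mapping):
                entries[name] = ParamEntry(
                    name,
                    float(spec["value"]),
                    str(spec.get("units", "")),
                    str(spec.get("provenance", "base")),
                )
            else:
                entries[name] = ParamEntry(name, float(spec))
        return cls(entries)

    def to_yaml_text(self) -> str:
        doc = {
            name: {
                "value": e.value,
                "units": e.units,
                "provenance": e.provenance,
            }
            for name, e in sorted(self._entries.items())
        }
        return yaml.safe_dump(doc, sort_keys=True)


def load_params(path) -> Params:
    with open(path, "r", encoding="utf-8") as fh:
        return Params.from_yaml_text(fh.read())


def load_default_params() -> Params:
    """Load the packaged default parameter table."""
    text = (
        importlib.resources.files("anls_ltp")
        .joinpath("data/default_params.yaml")
        .read_text(encoding="utf-8")
    )
    return Params.from_yaml_text(text)
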