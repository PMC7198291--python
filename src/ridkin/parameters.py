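"""Kinetic parameters of the whole-body vitamin A system.

A single subject's retinol kinetics are described by first-order fractional
transfer coefficients L(I,J) (fraction of compartment J transferred to
compartment I per day), an absorption delay, the efficiency with which an
oral dose reaches the delay, a constant dietary tracee input, and the size
of the labeled dose.  Compartment numbering follows the conventional
whole-body model: 4 = post-absorptive (chylomicron) retinyl ester,
5 = plasma retinol, 6 = larger slow-turnover store, 7 = smaller
fast-turnover store; component 3 is the absorption/processing delay and
component 8 the irreversible catabolic sink fed from plasma.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "KineticParameters",
    "RATE_NAMES",
    "PARAMETER_NAMES",
    "read_params",
    "write_params",
]

#: Fractional transfer coefficients, /d.
RATE_NAMES: tuple[str, ...] = (
    "l_5_4",
    "l_6_5",
    "l_7_5",
    "l_8_5",
    "l_5_6",
    "l_5_7",
    "l_0_6",
)

#: Every field of :class:`KineticParameters`, in declaration order.
PARAMETER_NAMES: tuple[str, ...] = (
    "absorption_efficiency",
    "delay_time",
    *RATE_NAMES,
    "dietary_intake",
    "dose",
)


@dataclass(frozen=True)
class KineticParameters:
    """One subject's vitamin A kinetic parameter set.

    Parameters
    ----------
    absorption_efficiency : float
        Fraction of an oral dose (and of dietary intake) that is absorbed,
        in (0, 1].
    delay_time : float
        Transit time through the absorption/chylomicron-processing delay
        (component 3), days; may be 0.
    l_5_4, l_6_5, l_7_5, l_8_5, l_5_6, l_5_7, l_0_6 : float
        Fractional transfer coefficients, /d; all strictly positive.
        ``l_8_5`` is irreversible loss from plasma via component 8 and
        ``l_0_6`` irreversible output from store 6.
    dietary_intake : float
        Unlabeled vitamin A intake at the absorption site, µmol/d; >= 0.
    dose : float
        Labeled dose administered orally at t = 0, µmol; > 0.
    """

    absorption_efficiency: float
    delay_time: float
    l_5_4: float
    l_6_5: float
    l_7_5: float
    l_8_5: float
    l_5_6: float
    l_5_7: float
    l_0_6: float
    dietary_intake: float
    dose: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.absorption_efficiency <= 1.0:
            raise ValueError(
                f"absorption_efficiency must be in (0, 1], got "
                f"{self.absorption_efficiency!r}"
            )
        if self.delay_time < 0.0:
            raise ValueError(f"delay_time must be >= 0, got {self.delay_time!r}")
        for name in RATE_NAMES:
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(f"rate constant {name} must be > 0, got {value!r}")
        if self.dietary_intake < 0.0:
            raise ValueError(
                f"dietary_intake must be >= 0, got {self.dietary_intake!r}"
            )
        if not self.dose > 0.0:
            raise ValueError(f"dose must be > 0, got {self.dose!r}")

    def replace(self, **changes: float) -> "KineticParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAMETER_NAMES}

    @classmethod
    def from_dict(cls, data: dict) -> "KineticParameters":
        """Build from a mapping with exactly the documented field names.

        Unknown keys are rejected so that typos in config files fail loudly
        instead of silently falling back to defaults.
        """
        unknown = set(data) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(
                f"unknown parameter keys: {sorted(unknown)}; "
                f"expected a subset of {list(PARAMETER_NAMES)}"
            )
        missing = set(PARAMETER_NAMES) - {"dose"} - set(data)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()})


def read_params(path: str | Path) -> KineticParameters:
    """Read a parameter set from a YAML (``.yaml``/``.yml``) or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of parameter fields")
    return KineticParameters.from_dict(data)


def write_params(params: KineticParameters, path: str | Path) -> None:
    """Write a parameter set to YAML or JSON, chosen by file suffix."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
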