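"""Per-patient kinetic parameters of the FT4 model.

The FT4 trajectory under a constant daily anti-thyroid-drug (ATD) dose ``d``
is governed by four patient-specific constants:

``a``
    synthesis rate of free thyroxine (day^-1),
``c``
    second-order decay rate (l pmol^-1 day^-1),
``ic50``
    daily dose producing half-maximal inhibition of FT4 synthesis (mg),
``c1``
    integration constant of the closed-form solution (l pmol^-1); it must be
    strictly negative for the trajectory to be positive and decreasing.

Published per-patient formulas are often printed in *product* form — the
grouped quantities ``a*ic50`` and ``a*ic50*c1`` together with ``ic50`` and
``c`` — because those are what enter the closed-form solution.
:meth:`ModelParams.from_products` reconstructs the primitive constants from
that form.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Any

from .exceptions import DomainError

#: Default strictness margin for the sign conditions in fitting and
#: validity checks (c1 <= -eps etc.). Construction of ModelParams itself
#: enforces only strict signs, so legitimately tiny magnitudes (a nearly
#: flat trajectory) remain representable.
DEFAULT_MARGIN = 1e-8

#: Clinical upper bound on ic50 (mg) used throughout estimation.
IC50_MAX = 150.0


@dataclass(frozen=True)
class ModelParams:
    """The four per-patient constants of the FT4 dose-response model.

    Parameters
    ----------
    a : float
        FT4 synthesis rate, day^-1. Strictly positive.
    c : float
        FT4 decay rate, l pmol^-1 day^-1. Strictly positive.
    ic50 : float
        Dose of half-maximal synthesis inhibition, mg. In (0, 150].
    c1 : float
        Integration constant, l pmol^-1. Strictly negative.
    meta : dict, optional
        Provenance metadata (patient id, fit date, objective value ...).
        Not part of equality or serialization identity checks.
    """

    a: float
    c: float
    ic50: float
    c1: float
    meta: dict = dataclasses.field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, margin: float = 0.0) -> None:
        """Raise :class:`DomainError` unless all sign/bound invariants hold."""
        for name in ("a", "c", "ic50", "c1"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"{name} must be finite, got {v!r}")
        if self.a <= 0:
            raise DomainError(f"a must be positive, got {self.a}")
        if self.c <= 0:
            raise DomainError(f"c must be positive, got {self.c}")
        if not (0 < self.ic50 <= IC50_MAX):
            raise DomainError(f"ic50 must lie in (0, {IC50_MAX}], got {self.ic50}")
        if not (self.c1 < 0 and self.c1 <= -margin):
            raise DomainError(
                f"c1 must be negative (<= -{margin:g}), got {self.c1}"
            )

    # -- product (printed-formula) form -------------------------------------

    @property
    def a_ic50(self) -> float:
        """The grouped rate constant a*ic50 as printed in report formulas."""
        return self.a * self.ic50

    @property
    def a_ic50_c1(self) -> float:
        """The grouped product a*ic50*c1 as printed in report formulas."""
        return self.a * self.ic50 * self.c1

    @classmethod
    def from_products(
        cls,
        a_ic50: float,
        c: float,
        a_ic50_c1: float,
        ic50: float,
        meta: dict | None = None,
    ) -> "ModelParams":
        """Build from the grouped products of a printed FT4 formula.

        This is the faithful way to reconstruct a published per-patient
        formula: the printed products carry more significant figures of the
        quantities that actually enter the solution than the individually
        rounded constants do.
        """
        if ic50 <= 0:
            raise DomainError(f"ic50 must be positive, got {ic50}")
        if a_ic50 <= 0:
            raise DomainError(f"a*ic50 must be positive, got {a_ic50}")
        a = a_ic50 / ic50
        c1 = a_ic50_c1 / a_ic50
        return cls(a=a, c=c, ic50=ic50, c1=c1, meta=meta or {})

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"a": self.a, "c": self.c, "ic50": self.ic50, "c1": self.c1}
        if self.meta:
            d["meta"] = dict(self.meta)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        return cls(
            a=float(d["a"]),
            c=float(d["c"]),
            ic50=float(d["ic50"]),
            c1=float(d["c1"]),
            meta=dict(d.get("meta", {})),
        )

    def to_json(self, path=None) -> str:
        """Serialize to a flat JSON document; write to ``path`` if given."""
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str) -> "ModelParams":
        """Read from a JSON string or a path to a JSON file."""
        s = str(source)
        if s.lstrip().startswith("{"):
            return cls.from_dict(json.loads(s))
        with open(s, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
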