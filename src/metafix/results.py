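"""Result container shared by all fixation-probability routes."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = ["FixationResult"]

METHODS = ("exact", "lowmig", "bipartite", "simulated", "closed_form")


@dataclass(frozen=True)
class FixationResult:
    """A fixation probability with provenance.

    ``se`` and ``n_replicates`` are present only for simulated estimates.
    """

    phi: float
    method: str
    params: dict = field(default_factory=dict)
    se: float | None = None
    n_replicates: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not -1e-12 <= self.phi <= 1.0 + 1e-12:
            raise ValueError(f"phi out of [0, 1]: {self.phi!r}")
        if (self.se is not None) != (self.method == "simulated"):
            raise ValueError("standard error is present iff method='simulated'")

    def to_dict(self) -> dict:
        d = {"phi": self.phi, "method": self.method, "params": dict(self.params)}
        if self.se is not None:
            d["se"] = self.se
            d["n_replicates"] = self.n_replicates
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)
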