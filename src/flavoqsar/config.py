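"""Run configuration: every tunable of the pipeline in one serializable object."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class RunConfig:
    """Tunables with their package-wide defaults.

    Serialized into every output artifact for provenance.
    """

    # descriptor engine
    rdf_b: float = 100.0            # RDF smoothing, Å⁻²
    rdf_eval_at: str = "midpoint"   # kernel evaluation point per bin
    # charge model
    peoe_iterations: int = 6
    peoe_damping: float = 0.5
    # selection cascade
    corr_min: float = 0.1           # relevance filter on |r(descriptor, y)|
    pair_max: float = 0.85          # redundancy filter on pairwise |r|
    p_enter: float = 0.05
    p_remove: float = 0.10
    # classification boundary convention (strong/active, active/inducer)
    class_boundaries: tuple = (-1.0, 0.0)
    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_boundaries"] = list(self.class_boundaries)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "class_boundaries" in d:
            d["class_boundaries"] = tuple(d["class_boundaries"])
        allowed = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in allowed})
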