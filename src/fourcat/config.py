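"""Pipeline configuration and the experiment manifest.

`PipelineConfig` gathers every analysis threshold in one serialisable
object: the 2 kb interaction window, the 1 Mb comparison bin, the adjusted
p-value cutoff 0.05, the |log2FC| > 1 differential cutoff, the > 40%
cis/overall QC gate, the > 0.4 replicate-correlation gate, and the
<= 1000 bp candidate-enhancer width cap.

`ExperimentManifest` crosses viewpoints x conditions x replicates into the
sample sheet of a full run (e.g. 4 viewpoints x 2 muscles x 2 replicates =
16 libraries).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple


@dataclass
class PipelineConfig:
    window_size: int = 2_000            # bp, interaction-calling windows
    bin_size: int = 1_000_000           # bp, comparison/QC bins
    alpha: float = 0.05                 # adjusted p-value cutoff
    lfc_min: float = 1.0                # |log2FC| threshold for SDIS
    cis_gate: float = 0.40              # cis/overall QC gate (strict >)
    corr_gate: float = 0.40             # replicate Pearson gate (strict >)
    enhancer_width_cap: int = 1_000     # bp, candidate enhancer max width
    overlap_min: int = 1                # bp, peak-overlap predicate
    exclusion_radius: int = 10_000      # bp, viewpoint-proximal exclusion  # artifact-default
    background_span: int = 101          # windows, running-median span      # artifact-default
    background_floor: float = 0.5       # counts, background floor          # artifact-default
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_size", "bin_size", "enhancer_width_cap", "overlap_min",
                     "exclusion_radius", "background_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lfc_min < 0 or self.background_floor <= 0:
            raise ValueError("lfc_min must be >= 0 and background_floor > 0")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: Dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls.from_dict(data)

    def digest_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass(frozen=True)
class Sample:
    viewpoint: str
    condition: str
    replicate: str
    reads_path: Optional[str] = None

    @property
    def id(self) -> str:
        return f"{self.viewpoint}_{self.condition}_{self.replicate}"


@dataclass
class ExperimentManifest:
    samples: List[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        triples = [(s.viewpoint, s.condition, s.replicate) for s in self.samples]
        if len(triples) != len(set(triples)):
            raise ValueError("duplicate (viewpoint, condition, replicate) triples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def viewpoints(self) -> List[str]:
        return sorted({s.viewpoint for s in self.samples})

    def conditions(self) -> List[str]:
        return sorted({s.condition for s in self.samples})

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(s.viewpoint, s.condition, s.replicate, s.reads_path) for s in self.samples],
            columns=["viewpoint", "condition", "replicate", "reads_path"],
        )


def build_manifest(
    viewpoints: Sequence[str],
    conditions: Sequence[str],
    replicates: "int | Sequence[str]",
) -> ExperimentManifest:
    """Full cross product of viewpoints x conditions x replicates.

    `replicates` is either a replicate count (labelled rep1..repN) or a list
    of replicate labels.  Deterministic order: viewpoint, condition, replicate.
    """
    if isinstance(replicates, int):
        if replicates < 1:
            raise ValueError("replicate count must be >= 1")
        rep_labels: List[str] = [f"rep{i}" for i in range(1, replicates + 1)]
    else:
        rep_labels = list(replicates)
    for label, values in [("viewpoints", viewpoints), ("conditions", conditions),
                          ("replicates", rep_labels)]:
        values = list(values)
        if not values:
            raise ValueError(f"{label} must be non-empty")
        if len(values) != len(set(values)):
            raise ValueError(f"duplicate names in {label}")
    samples = [
        Sample(v, c, r)
        for v in viewpoints
        for c in conditions
        for r in rep_labels
    ]
    return ExperimentManifest(samples=samples)
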