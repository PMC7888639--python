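"""Hard accession -> population assignments.

Used both for simulation ground truth and for inferred cluster membership.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass
class PopulationPartition:
    """Mapping from accession id to an integer cluster label in 1..k.

    ``confidence`` optionally carries the maximum ancestry coefficient of
    each accession (admixture confidence) when the partition comes from a
    model-based clustering.
    """

    assignments: dict[str, int]
    confidence: dict[str, float] | None = None

    def __post_init__(self):
        self.assignments = {str(a): int(c) for a, c in self.assignments.items()}
        if any(c < 1 for c in self.assignments.values()):
            raise ValueError("cluster labels must be >= 1")

    @property
    def n_accessions(self) -> int:
        return len(self.assignments)

    @property
    def n_populations(self) -> int:
        return len(set(self.assignments.values()))

    def labels(self) -> list[int]:
        return sorted(set(self.assignments.values()))

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.assignments.values():
            out[c] = out.get(c, 0) + 1
        return dict(sorted(out.items()))

    def members(self, label: int) -> list[str]:
        return [a for a, c in self.assignments.items() if c == label]

    def label_array(self, accessions) -> np.ndarray:
        """Cluster labels in the order of ``accessions`` (all must be mapped)."""
        try:
            return np.asarray([self.assignments[a] for a in accessions], dtype=int)
        except KeyError as exc:
            raise KeyError(f"accession {exc.args[0]!r} has no population label") from None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.confidence is None:
                fh.write("accession\tpopulation\n")
                for a, c in self.assignments.items():
                    fh.write(f"{a}\t{c}\n")
            else:
                fh.write("accession\tpopulation\tmax_q\n")
                for a, c in self.assignments.items():
                    fh.write(f"{a}\t{c}\t{self.confidence[a]:.6f}\n")

    @classmethod
    def from_tsv(cls, path) -> "PopulationPartition":
        df = pd.read_csv(path, sep="\t")
        conf = None
        if "max_q" in df.columns:
            conf = dict(zip(df["accession"].astype(str), df["max_q"].astype(float)))
        return cls(
            assignments=dict(zip(df["accession"].astype(str), df["population"].astype(int))),
            confidence=conf,
        )
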