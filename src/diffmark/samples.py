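"""Sample manifest: which track belongs to which genotype/antibody/replicate."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Iterator

__all__ = ["SampleInfo", "Manifest"]


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    genotype: str
    antibody: str  # "mark" (e.g. H3K27me3 IP) or "control" (e.g. H3 IP)
    replicate: int
    library_total: float  # total reads in the sample (sum of bedGraph values)
    seed: int | None = None


class Manifest:
    """Ordered collection of :class:`SampleInfo` with JSON round-trip."""

    def __init__(self, samples: Iterable[SampleInfo]):
        self.samples = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in manifest")

    def __iter__(self) -> Iterator[SampleInfo]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def genotypes(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.genotype not in seen:
                seen.append(s.genotype)
        return seen

    def select(self, genotype: str | None = None, antibody: str | None = None) -> list[SampleInfo]:
        out = []
        for s in self.samples:
            if genotype is not None and s.genotype != genotype:
                continue
            if antibody is not None and s.antibody != antibody:
                continue
            out.append(s)
        return out

    def to_json(self, path) -> None:
        payload = {"samples": [asdict(s) for s in self.samples]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "Manifest":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(SampleInfo(**entry) for entry in payload["samples"])
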