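"""Sample manifests: which slide pairs to process and where they live.

A manifest row describes one sample: a reticulin-like image, its H&E
counterpart, the image scale (microns per pixel) and an optional group
label.  Rows may instead carry a phantom spec, in which case the pipeline
simulates the pair at run time — that is the default way to exercise the
tool without real slides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["SampleEntry", "PairManifest"]


@dataclass
class SampleEntry:
    sample_id: str
    reticulin_path: str | None = None
    he_path: str | None = None
    mpp: float = 0.22
    group: str = "unspecified"
    phantom_spec: dict | None = None  # simulate instead of loading
    mask_paths: dict = field(default_factory=dict)


@dataclass
class PairManifest:
    samples: list[SampleEntry] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("manifest sample identifiers must be unique")
        for s in self.samples:
            if s.mpp <= 0:
                raise ValueError(f"sample {s.sample_id}: mpp must be positive")

    def validate_paths(self) -> None:
        for s in self.samples:
            if s.phantom_spec is not None:
                continue
            for label, p in (("reticulin", s.reticulin_path), ("he", s.he_path)):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"sample {s.sample_id}: missing {label} image {p!r}"
                    )

    @classmethod
    def from_json(cls, path) -> "PairManifest":
        data = json.loads(Path(path).read_text())
        return cls([SampleEntry(**row) for row in data["samples"]])

    def to_json(self, path) -> None:
        rows = [
            {
                "sample_id": s.sample_id,
                "reticulin_path": s.reticulin_path,
                "he_path": s.he_path,
                "mpp": s.mpp,
                "group": s.group,
                "phantom_spec": s.phantom_spec,
                "mask_paths": s.mask_paths,
            }
            for s in self.samples
        ]
        Path(path).write_text(json.dumps({"samples": rows}, indent=2))

    @classmethod
    def from_csv(cls, path) -> "PairManifest":
        df = pd.read_csv(path)
        samples = [
            SampleEntry(
                sample_id=str(r["sample_id"]),
                reticulin_path=r.get("reticulin_path"),
                he_path=r.get("he_path"),
                mpp=float(r.get("mpp", 0.22)),
                group=str(r.get("group", "unspecified")),
            )
            for r in df.to_dict("records")
        ]
        return cls(samples)
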