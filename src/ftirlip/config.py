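"""YAML-backed pipeline configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import yaml

from .bands import ESTER_CARBONYL, OLEFINIC, BandDefinition
from .preprocess import PreprocessConfig
from .spectra import ReaderDialect, WavenumberRegion

DEFAULT_RESPONSES = ["SAT", "MUFA", "PUFA", "unsaturation_index", "total_lipid"]


@dataclass
class PipelineConfig:
    spectra_path: Optional[str] = None
    gc_path: Optional[str] = None
    glucose_path: Optional[str] = None
    dialect: ReaderDialect = field(default_factory=ReaderDialect)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    bands: List[BandDefinition] = field(
        default_factory=lambda: [ESTER_CARBONYL, OLEFINIC]
    )
    responses: List[str] = field(default_factory=lambda: list(DEFAULT_RESPONSES))
    exclusions: List[Tuple[str, float, int]] = field(default_factory=list)
    max_ncomp: int = 25
    outdir: str = "ftirlip_out"
    seed: int = 2017

    def to_dict(self) -> dict:
        return {
            "inputs": {
                "spectra": self.spectra_path,
                "gc": self.gc_path,
                "glucose": self.glucose_path,
            },
            "dialect": {
                "layout": self.dialect.layout,
                "id_pattern": self.dialect.id_pattern,
                "delimiter": self.dialect.delimiter,
            },
            "preprocess": self.preprocess.to_dict(),
            "bands": [
                {
                    "name": b.name,
                    "center": b.center,
                    "window": [b.search_window.high, b.search_window.low],
                    "mode": b.mode,
                }
                for b in self.bands
            ],
            "responses": list(self.responses),
            "exclusions": [list(e) for e in self.exclusions],
            "max_ncomp": self.max_ncomp,
            "outdir": self.outdir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        inputs = d.get("inputs", {})
        dia = d.get("dialect", {})
        bands = [
            BandDefinition(
                name=b["name"],
                center=b["center"],
                search_window=WavenumberRegion(*b["window"]),
                mode=b.get("mode", "second-derivative-minimum"),
            )
            for b in d.get("bands", [])
        ] or [ESTER_CARBONYL, OLEFINIC]
        return cls(
            spectra_path=inputs.get("spectra"),
            gc_path=inputs.get("gc"),
            glucose_path=inputs.get("glucose"),
            dialect=ReaderDialect(
                layout=dia.get("layout", "wide"),
                id_pattern=dia.get("id_pattern", ReaderDialect().id_pattern),
                delimiter=dia.get("delimiter", ","),
            ),
            preprocess=PreprocessConfig.from_dict(d.get("preprocess", {})),
            bands=bands,
            responses=list(d.get("responses", DEFAULT_RESPONSES)),
            exclusions=[tuple(e) for e in d.get("exclusions", [])],
            max_ncomp=int(d.get("max_ncomp", 25)),
            outdir=d.get("outdir", "ftirlip_out"),
            seed=int(d.get("seed", 2017)),
        )

    def to_yaml(self, dest: Union[str, Path]) -> None:
        Path(dest).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(source).read_text()) or {})
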