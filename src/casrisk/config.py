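"""Run configuration: database paths per layer plus search parameters.

Any subset of annotation layers may be configured; omitted layers are
skipped with a logged notice.  Paths in a YAML config are resolved relative
to the config file's directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .sequence_search import SearchParams

logger = logging.getLogger(__name__)

DB_LAYERS = ("gene_models", "promoters", "enhancers", "regulator_peaks",
             "protein_domains", "mirna_genes", "mirna_targets",
             "phenotypes", "cancer_genes", "tf", "rbp", "expression")


@dataclass
class RunConfig:
    genome: Optional[Path] = None
    databases: dict[str, Path] = field(default_factory=dict)
    search: SearchParams = field(default_factory=SearchParams)
    pam: str = "NGG"
    promoter_upstream: int = 499
    promoter_downstream: int = 100
    out_dir: Path = Path("casrisk_out")
    formats: tuple[str, ...] = ("csv",)
    seed: int = 0

    def validate(self) -> None:
        """Check referenced paths exist; log which layers are absent."""
        if self.genome is not None and not Path(self.genome).exists():
            raise FileNotFoundError(f"genome not found: {self.genome}")
        for layer, path in self.databases.items():
            if layer not in DB_LAYERS:
                raise ValueError(f"unknown database layer {layer!r}; "
                                 f"expected one of {DB_LAYERS}")
            if not Path(path).exists():
                raise FileNotFoundError(f"database {layer!r} not found: {path}")
        for layer in DB_LAYERS:
            if layer not in self.databases:
                logger.info("annotation layer %r not configured; skipping", layer)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    Schema::

        genome: genome.fa
        databases:            # any subset of the known layers
          gene_models: genes.gff3
          promoters: promoters.bed
          ...
        search:
          pam: NGG
          max_mismatches: 4
          max_dna_bulges: 0
          max_rna_bulges: 0
        promoter_window:
          upstream: 499
          downstream: 100
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text()) or {}
    base = path.parent
    cfg = RunConfig()
    if doc.get("genome"):
        cfg.genome = base / doc["genome"]
    for layer, p in (doc.get("databases") or {}).items():
        cfg.databases[layer] = base / p
    s = doc.get("search") or {}
    cfg.pam = str(s.get("pam", cfg.pam)).upper()
    cfg.search = SearchParams(
        max_mismatches=int(s.get("max_mismatches", 4)),
        max_dna_bulges=int(s.get("max_dna_bulges", 0)),
        max_rna_bulges=int(s.get("max_rna_bulges", 0)),
        both_strands=bool(s.get("both_strands", True)),
    )
    w = doc.get("promoter_window") or {}
    cfg.promoter_upstream = int(w.get("upstream", cfg.promoter_upstream))
    cfg.promoter_downstream = int(w.get("downstream", cfg.promoter_downstream))
    return cfg
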