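"""File formats and run configuration.

Plain text throughout: TSV for tabular data (design, intensities, K_eq
tables, fit outputs), FASTA for target segments, YAML for the run
configuration and JSON for summaries.  Coordinates in files are 1-based
inclusive.  Output files carry a provenance comment header (tool version
and a hash of the configuration); comment lines starting with ``#`` are
ignored on input.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import ChipDesign, ProbeSpot
from .fit import FitConfig, FitResult
from .fragments import TargetSegment
from .hybridization import KeqTable
from .scanner import ScannerModel

__all__ = [
    "RunConfig",
    "load_config",
    "read_design",
    "write_design",
    "read_intensities",
    "write_intensities",
    "write_keq_table",
    "write_fit_result",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run settings; defaults mirror the modelled protocol
    (42 C, 1 M [Na+], scanner 100 / 65536 / shape 7)."""

    temperature_c: float = 42.0
    na_molar: float = 1.0
    scanner_min: float = 100.0
    scanner_max: float = 65536.0
    scanner_gomp: float = 7.0
    mean_fragment_size: list[float] = field(default_factory=lambda: [30.0, 50.0])
    wash_keqw: list[float] = field(default_factory=lambda: [0.0, 1e6])
    prune: float = 1e-12
    seed: int = 0
    fit_restarts: int = 2
    fit_tolerance: float = 1e-9
    fit_max_iterations: int = 150
    fit_objective_scale: str = "raw"

    def __post_init__(self) -> None:
        if self.temperature_c <= -273.15:
            raise ValueError("temperature below absolute zero")
        if self.na_molar <= 0:
            raise ValueError("na_molar must be positive")
        if not self.mean_fragment_size or min(self.mean_fragment_size) < 1:
            raise ValueError("mean_fragment_size grid must contain values >= 1")
        if not self.wash_keqw or min(self.wash_keqw) < 0:
            raise ValueError("wash_keqw grid must contain values >= 0")
        if self.prune < 0:
            raise ValueError("prune must be >= 0")
        ScannerModel(self.scanner_min, self.scanner_max, self.scanner_gomp)

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15

    def scanner(self) -> ScannerModel:
        return ScannerModel(self.scanner_min, self.scanner_max, self.scanner_gomp)

    def fit_config(self) -> FitConfig:
        return FitConfig(
            wash_grid=list(self.wash_keqw),
            frag_grid=list(self.mean_fragment_size),
            n_restarts=self.fit_restarts,
            seed=self.seed,
            tolerance=self.fit_tolerance,
            max_iterations=self.fit_max_iterations,
            objective_scale=self.fit_objective_scale,
        )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file; keyword arguments override file values."""
    values: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; known keys: {sorted(known)}"
        )
    return RunConfig(**values)


def _provenance(config: RunConfig | None) -> str:
    from . import __version__

    tag = f"# probeforest v{__version__}"
    if config is not None:
        tag += f" config={config.digest()}"
    return tag + "\n"


def read_design(
    design_tsv: str | Path, segments_fasta: str | Path, strict: bool = False
) -> ChipDesign:
    """Read a chip design from a probe TSV and a segments FASTA.

    Required TSV columns: probe_id, sequence, strand, segment_id; optional:
    locus, replicate_group.  FASTA record ids must match segment_id values.
    Sequences are uppercased; non-ACGT characters are rejected.
    """
    df = pd.read_csv(design_tsv, sep="\t", comment="#", dtype=str)
    required = ["probe_id", "sequence", "strand", "segment_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{design_tsv}: missing column(s) {missing}")
    segments = [
        TargetSegment(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(segments_fasta), "fasta")
    ]
    if not segments:
        raise ValueError(f"{segments_fasta}: no FASTA records")
    probes = []
    for row in df.itertuples(index=False):
        probes.append(
            ProbeSpot(
                probe_id=row.probe_id,
                sequence=row.sequence,
                strand=row.strand,
                segment_id=row.segment_id,
                locus=getattr(row, "locus", None) if "locus" in df.columns else None,
                replicate_group=(
                    row.replicate_group
                    if "replicate_group" in df.columns
                    and isinstance(row.replicate_group, str)
                    else None
                ),
            )
        )
    return ChipDesign(probes, segments, strict=strict)


def write_design(
    design: ChipDesign,
    design_tsv: str | Path,
    segments_fasta: str | Path,
    config: RunConfig | None = None,
) -> None:
    rows = [
        {
            "probe_id": p.probe_id,
            "sequence": p.sequence,
            "strand": p.strand,
            "segment_id": p.segment_id,
            "locus": p.locus if p.locus is not None else "",
            "replicate_group": p.replicate_group if p.replicate_group else "",
        }
        for p in design.probes
    ]
    with open(design_tsv, "w", encoding="utf-8") as fh:
        fh.write(_provenance(config))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    SeqIO.write(
        [SeqRecord(Seq(s.sequence), id=s.id, description="") for s in design.segments],
        str(segments_fasta),
        "fasta",
    )


def read_intensities(path: str | Path) -> dict[str, float]:
    """probe_id -> intensity map; NA values are preserved as missing keys."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"probe_id": str}, na_values=["NA", "nan"]
    )
    if not {"probe_id", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns probe_id, intensity")
    if len(df) == 0:
        raise ValueError(f"{path}: no intensity rows")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"{path}: duplicate probe_id {dup!r}")
    vals = pd.to_numeric(df["intensity"], errors="coerce")
    bad = vals.notna() & (vals < 0)
    if bad.any():
        raise ValueError(
            f"{path}: negative intensity for probe {df.loc[bad, 'probe_id'].iloc[0]!r}"
        )
    n_na = int(vals.isna().sum())
    if n_na:
        logger.info("%s: %d probe(s) with missing intensity", path, n_na)
    return {
        pid: float(v) for pid, v in zip(df["probe_id"], vals) if np.isfinite(v)
    }


def write_intensities(
    values: dict[str, float], path: str | Path, config: RunConfig | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(config))
        fh.write("probe_id\tintensity\n")
        for pid, v in values.items():
            fh.write(f"{pid}\t{v:.6g}\n")


def write_keq_table(
    table: KeqTable, path: str | Path, config: RunConfig | None = None
) -> None:
    out = table.entries.copy()
    out.insert(0, "probe_variant_id", table.probe_variant_id)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(config))
        out.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def write_fit_result(
    result: FitResult,
    out_prefix: str | Path,
    observed: dict[str, float] | None = None,
    config: RunConfig | None = None,
) -> None:
    """Write <prefix>.params.tsv, <prefix>.predicted.tsv, <prefix>.json."""
    prefix = str(out_prefix)
    with open(prefix + ".params.tsv", "w", encoding="utf-8") as fh:
        fh.write(_provenance(config))
        fh.write("parameter\tvalue\n")
        for b in "ACGT":
            fh.write(f"{b}_incorporation\t{result.synthesis.incorporation[b]:.6f}\n")
        for b in "ACGT":
            fh.write(f"{b}_retention\t{result.synthesis.retention[b]:.6f}\n")
        for seg, c in result.concentrations.items():
            fh.write(f"concentration_{seg}\t{c:.6g}\n")
        fh.write(f"mean_fragment_size\t{result.mu:.6g}\n")
        fh.write(f"wash_keqw\t{result.keqw:.6g}\n")
    with open(prefix + ".predicted.tsv", "w", encoding="utf-8") as fh:
        fh.write(_provenance(config))
        fh.write("probe_id\texpected\tobserved\n")
        for pid, v in result.predicted.items():
            obs = observed.get(pid, float("nan")) if observed else float("nan")
            fh.write(f"{pid}\t{v:.6g}\t{obs:.6g}\n")
    summary = {
        "objective": result.objective,
        "pearson_r": result.pearson_r,
        "pearson_r_log": result.pearson_r_log,
        "mu": result.mu,
        "keqw": result.keqw,
        "converged": result.converged,
        "n_missing_observations": result.n_missing_observations,
        "incorporation": result.synthesis.incorporation,
        "retention": result.synthesis.retention,
        "concentrations": result.concentrations,
    }
    with open(prefix + ".json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
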