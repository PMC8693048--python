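"""Configuration, run manifests, and readers/writers for the documented
file dialects (.smi libraries, CSV synergy tables, TSV expression matrices,
CSV target profiles, candidate tables).

All run-level randomness flows through named seeds recorded in the
manifest, so any run can be regenerated bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chem import MoleculeRecord, StructureRejected, clean_structure
from .mechanism import TargetProfile
from .sdsp import SynergySample

__all__ = [
    "RunConfig", "load_config", "config_hash", "write_manifest",
    "read_smi", "write_smi", "read_synergy_csv", "read_target_profiles_csv",
    "write_candidates_csv", "ValidationReport",
]

EXIT_OK, EXIT_VALIDATION, EXIT_NUMERIC = 0, 2, 3


@dataclass
class RunConfig:
    """Flat run configuration: seeds, paths, hyperparameters, thresholds.

    Unknown keys in a config file are rejected by name so typos surface
    immediately.
    """

    seed: int = 0
    n_scaffolds: int = 100
    temperature: float = 1.0
    synergy_threshold: float = 5.0
    deg_threshold: float = 1.0
    gsg: dict = field(default_factory=dict)     # GSGConfig overrides
    sdsp: dict = field(default_factory=dict)    # SDSPConfig overrides
    augment: dict = field(default_factory=dict) # AugmentationConfig overrides
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """YAML config -> RunConfig with defaults filled; empty file = defaults;
    unknown keys raise with the offending key path."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    return RunConfig(**raw)


def config_hash(cfg: RunConfig | dict) -> str:
    """Stable short hash of a config (key order independent)."""
    d = cfg.to_dict() if isinstance(cfg, RunConfig) else dict(cfg)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(path, config: RunConfig | dict, inputs: list = (), outputs: list = (),
                   seeds: dict | None = None, status: str = "ok",
                   failure_stage: str | None = None) -> dict:
    """JSON run manifest: config hash, seeds, input digests, outputs,
    versions, status (and failure stage for aborted runs)."""
    manifest = {
        "config": (config.to_dict() if isinstance(config, RunConfig) else dict(config)),
        "config_hash": config_hash(config),
        "seeds": dict(seeds or {}),
        "inputs": {str(p): _file_digest(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
        "versions": {"python": platform.python_version(), "numpy": np.__version__},
        "status": status,
    }
    if failure_stage:
        manifest["failure_stage"] = failure_stage
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------- tables
@dataclass
class ValidationReport:
    """Aggregated row-level problems, each as (line number, message)."""

    errors: list = field(default_factory=list)

    def add(self, line: int, message: str) -> None:
        self.errors.append((line, message))

    def raise_if_over(self, tolerance: int = 0) -> None:
        if len(self.errors) > tolerance:
            detail = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:5])
            raise ValueError(f"{len(self.errors)} malformed row(s): {detail}")


def read_smi(path, clean: bool = True, tolerance: int | None = None
             ) -> tuple[list[MoleculeRecord], ValidationReport]:
    """Read a .smi file (one SMILES per line, optional tab-separated id;
    CRLF tolerated).  With ``clean`` the structures are canonicalized and
    filtered; bad rows go to the report, which raises if more than
    ``tolerance`` (default: unlimited) accumulate."""
    report = ValidationReport()
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smi = parts[0].strip()
        mol_id = parts[1].strip() if len(parts) > 1 else f"L{ln}"
        if clean:
            try:
                rec = clean_structure(smi, mol_id=mol_id)
            except StructureRejected as exc:
                report.add(ln, f"{smi!r}: {exc.reason}")
                continue
        else:
            rec = MoleculeRecord(smiles=smi, id=mol_id)
        if rec.smiles in seen:
            continue
        seen.add(rec.smiles)
        records.append(rec)
    if tolerance is not None:
        report.raise_if_over(tolerance)
    return records, report


def write_smi(path, records: list[MoleculeRecord]) -> None:
    Path(path).write_text("".join(f"{r.smiles}\t{r.id}\n" for r in records))


def read_synergy_csv(path, cell_profiles: dict | None = None, tolerance: int | None = None
                     ) -> tuple[list[SynergySample], ValidationReport]:
    """CSV with columns drugA_smiles, drugB_smiles, cell_id, bliss.

    ``cell_profiles`` maps cell_id -> expression vector; absent ids get a
    zero vector (and a report entry) so shape contracts still hold.
    """
    df = pd.read_csv(path)
    required = {"drugA_smiles", "drugB_smiles", "cell_id", "bliss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    report = ValidationReport()
    samples: list[SynergySample] = []
    n_genes = (len(next(iter(cell_profiles.values()))) if cell_profiles else 978)
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            a = clean_structure(str(row["drugA_smiles"])).smiles
            b = clean_structure(str(row["drugB_smiles"])).smiles
        except StructureRejected as exc:
            report.add(line, exc.reason)
            continue
        cid = str(row["cell_id"])
        if cell_profiles and cid in cell_profiles:
            cell = np.asarray(cell_profiles[cid], dtype=float)
        else:
            if cell_profiles is not None:
                report.add(line, f"unknown cell id {cid!r}")
            cell = np.zeros(n_genes)
        samples.append(SynergySample(a, b, cell, float(row["bliss"]), cid))
    if tolerance is not None:
        report.raise_if_over(tolerance)
    return samples, report


def read_target_profiles_csv(path) -> dict[str, TargetProfile]:
    """CSV with columns drug_id, target_id -> {drug_id: TargetProfile}."""
    df = pd.read_csv(path)
    missing = {"drug_id", "target_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[str, TargetProfile] = {}
    for drug, grp in df.groupby("drug_id"):
        out[str(drug)] = TargetProfile(str(drug), frozenset(grp["target_id"].astype(str)))
    return out


def write_candidates_csv(path, candidates) -> None:
    rows = [{
        "rank": i + 1,
        "drugA": c.drugA.smiles,
        "drugB": c.drugB.smiles,
        "cell_id": c.cell_id,
        "score": c.score,
        "scaffolds": ";".join(c.scaffolds),
    } for i, c in enumerate(candidates)]
    pd.DataFrame(rows, columns=["rank", "drugA", "drugB", "cell_id", "score", "scaffolds"]
                 ).to_csv(path, index=False)
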