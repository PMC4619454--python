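"""File formats: SMILES/SDF input, bioactivity tables, class files,
threshold files and prediction output.

All tabular artifacts are plain delimited text; every written artifact
gets a JSON provenance sidecar (``<file>.provenance.json``) recording
the configuration and seed that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .training import BioactivityRecord, TargetClass

#: Default mapping from the package's record fields to table columns.
DEFAULT_COLUMN_MAP = {
    "compound_id": "compound_id",
    "structure": "structure",
    "target_id": "target_id",
    "activity_type": "activity_type",
    "value_um": "value_um",
    "confidence": "confidence",
    "reported_label": "reported_label",
}


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a .smi file (``SMILES<TAB>id`` per line, ``#`` comments).

    Lines without an explicit id get a 1-based positional one.
    """
    out: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
        out.append((mol_id, smiles))
    return out


def write_smiles_file(path, entries: list[tuple[str, str]]) -> None:
    """Write (id, SMILES) pairs back in the same ``SMILES<TAB>id`` dialect."""
    with open(path, "w") as fh:
        for mol_id, smiles in entries:
            fh.write(f"{smiles}\t{mol_id}\n")


def read_sdf(path, id_property: str = "_Name") -> list[tuple[str, str]]:
    """Read an SDF into (id, SMILES) pairs; unparsable entries are skipped."""
    out = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        if id_property != "_Name" and mol.HasProp(id_property):
            mol_id = mol.GetProp(id_property)
        else:
            mol_id = mol.GetProp("_Name") or f"sdf{i + 1}"
        out.append((mol_id, Chem.MolToSmiles(mol)))
    return out


def read_bioactivity_table(
    path, sep: str = "\t", column_map: dict[str, str] | None = None
) -> list[BioactivityRecord]:
    """Read delimited bioactivity records with a configurable column map."""
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"bioactivity table {path} lacks columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        value = d[cmap["value_um"]]
        records.append(
            BioactivityRecord(
                compound_id=str(d[cmap["compound_id"]]),
                structure=str(d[cmap["structure"]]),
                target_id=str(d[cmap["target_id"]]),
                activity_type=str(d[cmap["activity_type"]]),
                value_um=None if pd.isna(value) else float(value),
                confidence=int(d[cmap["confidence"]]),
                reported_label=str(d[cmap["reported_label"]]),
            )
        )
    return records


def _bits_to_str(fp: np.ndarray) -> str:
    return ",".join(str(i) for i in np.flatnonzero(fp))


def _str_to_bits(s: str, length: int) -> np.ndarray:
    fp = np.zeros(length, dtype=np.uint8)
    if s:
        fp[[int(tok) for tok in s.split(",")]] = 1
    return fp


def write_class_file(path, cls: TargetClass, fp_length: int,
                     provenance: dict | None = None) -> None:
    """Per-target class file: compound id, label, origin, on-bit indices.

    A JSON sidecar records seed/radius/ratio provenance.
    """
    with open(path, "w") as fh:
        fh.write("compound_id\tlabel\torigin\tbits\n")
        for cid, fp in zip(cls.active_ids, cls.active_fps):
            fh.write(f"{cid}\tactive\tactive\t{_bits_to_str(fp)}\n")
        for cid, fp, origin in zip(cls.inactive_ids, cls.inactive_fps,
                                   cls.inactive_origin):
            fh.write(f"{cid}\tinactive\t{origin}\t{_bits_to_str(fp)}\n")
    sidecar = {"target_id": cls.target_id, "fp_length": fp_length,
               "n_active": cls.n_active, "n_inactive": cls.n_inactive,
               **cls.provenance, **(provenance or {})}
    Path(str(path) + ".provenance.json").write_text(json.dumps(sidecar, indent=2))


def read_class_file(path) -> TargetClass:
    """Read a class file written by :func:`write_class_file`."""
    sidecar = json.loads(Path(str(path) + ".provenance.json").read_text())
    length = sidecar["fp_length"]
    a_ids, a_fps, i_ids, i_fps, origins = [], [], [], [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("compound_id"):
            raise ValueError(f"malformed class file {path}: bad header")
        for line in fh:
            cid, label, origin, bits = line.rstrip("\n").split("\t")
            fp = _str_to_bits(bits, length)
            if label == "active":
                a_ids.append(cid)
                a_fps.append(fp)
            else:
                i_ids.append(cid)
                i_fps.append(fp)
                origins.append(origin)
    return TargetClass(
        target_id=sidecar["target_id"],
        active_ids=a_ids,
        active_fps=np.vstack(a_fps) if a_fps else np.empty((0, length), np.uint8),
        inactive_ids=i_ids,
        inactive_fps=np.vstack(i_fps) if i_fps else np.empty((0, length), np.uint8),
        inactive_origin=origins,
        provenance={k: v for k, v in sidecar.items()
                    if k not in {"target_id", "fp_length", "n_active", "n_inactive"}},
    )


def write_threshold_file(path, threshold_sets) -> None:
    """Delimited thresholds: target_id, metric, threshold, metric value."""
    with open(path, "w") as fh:
        fh.write("target_id\tmetric\tthreshold\tmean_metric_at_optimum\n")
        for ts in threshold_sets:
            for metric, value in ts.thresholds.items():
                at_opt = ts.metric_at_optimum.get(metric, float("nan"))
                fh.write(f"{ts.target_id}\t{metric}\t{value:.3f}\t{at_opt:.6f}\n")


def read_threshold_file(path) -> dict[str, dict[str, float]]:
    """Thresholds as {target_id: {metric: threshold}}."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.target_id), {})[str(row.metric)] = float(row.threshold)
    return out


def write_provenance(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
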