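"""Structure standardization, filtering, fingerprinting and similarity.

Compounds enter the pipeline as SMILES, are standardized to a single
canonical largest-fragment representation, filtered on molecular weight
and elemental composition, and encoded as fixed-length binary Morgan
(ECFP_4-equivalent, radius 2) fingerprints.  Similarity between
fingerprints is the Tanimoto coefficient over set bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Elements excluded from training structures.  The list intentionally
#: mixes halogens with metals/metalloids; it is exposed as configuration
#: because excluding F and Br is unusual for drug-like chemistry.
DEFAULT_DISALLOWED_ELEMENTS: frozenset[str] = frozenset(
    {"Li", "Be", "B", "F", "Na", "Al", "Si", "Ar", "Ti", "Fe", "Zn", "Br"}
)

DEFAULT_MW_LOW = 100.0
DEFAULT_MW_HIGH = 900.0
DEFAULT_FP_RADIUS = 2
DEFAULT_FP_BITS = 2048


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; names the offending id."""


@dataclass(frozen=True)
class Molecule:
    """A standardized compound: opaque id, canonical SMILES, weight in Da."""

    id: str
    structure: str
    mw: float


_largest_fragment = rdMolStandardize.LargestFragmentChooser()
_uncharger = rdMolStandardize.Uncharger()
_tautomerizer = rdMolStandardize.TautomerEnumerator()


def standardize(raw_structure: str, mol_id: str = "") -> Molecule:
    """Standardize a raw SMILES string into a canonical :class:`Molecule`.

    The pipeline keeps the largest covalent fragment (salts/counter-ions
    dropped), neutralizes charges where chemically valid, strips explicit
    hydrogens, and picks one canonical tautomer deterministically.  The
    same input always yields a byte-identical canonical SMILES, and the
    operation is idempotent.

    Raises
    ------
    StructureParseError
        If the input is empty or does not parse, with ``mol_id`` in the
        message.
    """
    if not raw_structure or not raw_structure.strip():
        raise StructureParseError(f"empty structure for compound {mol_id!r}")
    mol = Chem.MolFromSmiles(raw_structure)
    if mol is None:
        raise StructureParseError(
            f"unparseable structure for compound {mol_id!r}: {raw_structure!r}"
        )
    mol = _largest_fragment.choose(mol)
    mol = _uncharger.uncharge(mol)
    mol = Chem.RemoveHs(mol)
    mol = _tautomerizer.Canonicalize(mol)
    smiles = Chem.MolToSmiles(mol)
    return Molecule(id=mol_id, structure=smiles, mw=Descriptors.MolWt(mol))


def passes_structure_filters(
    mol: Molecule,
    mw_low: float = DEFAULT_MW_LOW,
    mw_high: float = DEFAULT_MW_HIGH,
    disallowed_elements: frozenset[str] = DEFAULT_DISALLOWED_ELEMENTS,
) -> tuple[bool, str]:
    """Check the training-set structure filters; return (ok, reason).

    A molecule passes iff its weight lies strictly inside
    (``mw_low``, ``mw_high``) Da, it contains at least one carbon atom,
    and it contains none of the disallowed elements.  ``reason`` names
    the first failed rule (``"mw_low"``, ``"mw_high"``, ``"no_carbon"``,
    ``"disallowed_element"``) or is ``"ok"``.
    """
    if mol.mw <= mw_low:
        return False, "mw_low"
    if mol.mw >= mw_high:
        return False, "mw_high"
    rdmol = Chem.MolFromSmiles(mol.structure)
    if rdmol is None:  # pragma: no cover - standardized structures parse
        raise StructureParseError(f"unparseable structure for compound {mol.id!r}")
    symbols = {atom.GetSymbol() for atom in rdmol.GetAtoms()}
    if "C" not in symbols:
        return False, "no_carbon"
    if symbols & disallowed_elements:
        return False, "disallowed_element"
    return True, "ok"


def fingerprint(
    mol: Molecule,
    radius: int = DEFAULT_FP_RADIUS,
    n_bits: int = DEFAULT_FP_BITS,
) -> np.ndarray:
    """Hashed circular Morgan fingerprint as a uint8 0/1 vector.

    Radius 2 with 2048 bits corresponds to the ECFP_4 configuration.
    Deterministic: identical structures give identical fingerprints.
    """
    rdmol = Chem.MolFromSmiles(mol.structure)
    if rdmol is None:
        raise StructureParseError(
            f"cannot fingerprint compound {mol.id!r}: structure does not parse"
        )
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(rdmol).astype(np.uint8)


def fingerprint_smiles(
    raw: str,
    mol_id: str = "",
    radius: int = DEFAULT_FP_RADIUS,
    n_bits: int = DEFAULT_FP_BITS,
) -> np.ndarray:
    """Standardize then fingerprint in one step (convenience for queries)."""
    return fingerprint(standardize(raw, mol_id), radius=radius, n_bits=n_bits)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| between two binary fingerprints.

    Two all-zero fingerprints are defined as maximally similar (1.0).
    Raises ``ValueError`` on length mismatch.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return inter / union


def bulk_tanimoto(query: np.ndarray, fps: np.ndarray) -> np.ndarray:
    """Tanimoto of one query fingerprint against a (n, length) matrix."""
    query = np.asarray(query)
    fps = np.asarray(fps)
    if fps.ndim != 2 or fps.shape[1] != query.shape[0]:
        raise ValueError(
            f"fingerprint length mismatch: query {query.shape} vs matrix {fps.shape}"
        )
    q = query.astype(np.int64)
    m = fps.astype(np.int64)
    inter = m @ q
    union = m.sum(axis=1) + q.sum() - inter
    out = np.ones(len(fps), dtype=np.float64)  # union 0 => both empty => 1.0
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


def pairwise_tanimoto(fps: np.ndarray) -> np.ndarray:
    """Symmetric (n, n) Tanimoto matrix for a fingerprint matrix."""
    m = np.asarray(fps).astype(np.int64)
    inter = m @ m.T
    counts = m.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim
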