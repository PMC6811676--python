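"""Read multi-model nucleic-acid PDB files into an ensemble representation.

Parsing is delegated to gemmi (gzip-transparent, tolerant of the usual PDB
dialect quirks); this module flattens the hierarchy into plain dictionaries
keyed by (chain, residue number) and normalized atom names, which is what
the geometry analyses need.  Coordinates are in angstroms, residue
numbering as authored in the file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "ModelEnsemble",
    "read_pdb_models",
    "extract_ring_torsions",
    "normalize_atom_name",
    "RING_ATOMS",
]

#: furanose ring atoms in endocyclic-torsion order
RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")

_PRIME_CHARS = {"′": "'", "’": "'", "*": "'"}


def normalize_atom_name(name: str) -> str:
    """Normalize PDB atom-name dialects to a canonical prime spelling.

    Typographic primes and ``*`` become ``'``; a leading digit is rotated to
    the end (``1H2'`` -> ``H2'1``), after which a trailing ``1`` on an
    otherwise unique proton name is dropped (``H1'1`` -> ``H1'``) and
    ``H2'2`` becomes ``H2''``.  Idempotent.
    """
    out = name.strip()
    for bad, good in _PRIME_CHARS.items():
        out = out.replace(bad, good)
    if out and out[0].isdigit():
        out = out[1:] + out[0]
    if out == "H2'2":
        out = "H2''"
    elif out.endswith("'1") and len(out) > 2:
        out = out[:-1]
    return out


@dataclass
class ModelEnsemble:
    """Ordered models; each maps (chain, resnum) -> residue atom table.

    ``models[i][(chain, resnum)]`` is a dict with keys ``name`` (residue
    name) and ``atoms`` (normalized atom name -> (3,) coordinate array) and
    ``elements`` (atom name -> element symbol).
    """

    models: list[dict]
    entry_id: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("an ensemble needs at least one model")

    @property
    def n_models(self) -> int:
        return len(self.models)

    @staticmethod
    def parse_selector(selector: str) -> tuple[str, int]:
        """Parse a "chain:resnum" residue selector."""
        chain, _, num = selector.partition(":")
        if not num:
            raise ValueError(f"bad residue selector {selector!r}; expected 'chain:resnum'")
        return chain, int(num)

    def residue(self, model_index: int, selector: str) -> dict:
        key = self.parse_selector(selector)
        model = self.models[model_index]
        if key not in model:
            raise KeyError(f"residue {selector!r} not present in model {model_index}")
        return model[key]

    def atom_coords(self, model_index: int, selector: str, atom_name: str) -> np.ndarray:
        res = self.residue(model_index, selector)
        name = normalize_atom_name(atom_name)
        if name not in res["atoms"]:
            raise KeyError(
                f"atom {name!r} missing from residue {selector!r} "
                f"({res['name']}) in model {model_index}"
            )
        return res["atoms"][name]

    def elements(self) -> set[str]:
        """All element symbols present in the first model."""
        out: set[str] = set()
        for res in self.models[0].values():
            out.update(res["elements"].values())
        return out

    def common_atom_keys(self, heavy_only: bool = True) -> list[tuple[str, int, str]]:
        """(chain, resnum, atom name) keys present in every model, sorted."""
        keysets = []
        for model in self.models:
            s = set()
            for (chain, num), res in model.items():
                for name in res["atoms"]:
                    if heavy_only and res["elements"].get(name, "") == "H":
                        continue
                    s.add((chain, num, name))
            keysets.append(s)
        common = set.intersection(*keysets)
        return sorted(common)


def read_pdb_models(path: str | Path) -> ModelEnsemble:
    """Read a (possibly gzipped) multi-model PDB file into a ModelEnsemble.

    One ensemble entry per MODEL block; files without MODEL records yield an
    ensemble of one.  HETATM records (e.g. Hg) are retained.  Alternate
    locations resolve to the highest occupancy, ties broken by label order.
    If models disagree on their residue sets a warning is emitted and the
    intersection is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
    models: list[dict] = []
    for model in structure:
        table: dict = {}
        for chain in model:
            for residue in chain:
                key = (chain.name, residue.seqid.num)
                atoms: dict[str, np.ndarray] = {}
                elements: dict[str, str] = {}
                occupancy: dict[str, float] = {}
                for atom in residue:
                    name = normalize_atom_name(atom.name)
                    occ = atom.occ
                    if name in atoms and occ <= occupancy[name]:
                        continue  # altloc: highest occupancy wins, first label on tie
                    atoms[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    elements[name] = atom.element.name
                    occupancy[name] = occ
                table[key] = {"name": residue.name, "atoms": atoms, "elements": elements}
        models.append(table)
    if not models:
        raise ValueError(f"no models found in {path}")
    residue_sets = [set(m.keys()) for m in models]
    common = set.intersection(*residue_sets)
    if any(s != common for s in residue_sets):
        warnings.warn(
            f"{path.name}: models disagree on residue sets; "
            f"using the intersection ({len(common)} residues)"
        )
        models = [{k: m[k] for k in sorted(common)} for m in models]
    return ModelEnsemble(models=models, entry_id=structure.name or path.stem)


def extract_ring_torsions(ensemble: ModelEnsemble, model_index: int, selector: str):
    """Five endocyclic sugar torsions of one residue, standard nu0..nu4 order.

    nu0 = C4'-O4'-C1'-C2' ... nu4 = C3'-C4'-O4'-C1'.  A missing ring atom
    raises with the atom named.
    """
    from .ring_geometry import RingTorsions, dihedral_from_coords

    res = ensemble.residue(model_index, selector)
    coords = {}
    for name in RING_ATOMS:
        if name not in res["atoms"]:
            raise ValueError(
                f"residue {selector!r} in model {model_index} is missing "
                f"ring atom {name!r}"
            )
        coords[name] = res["atoms"][name]
    ring = list(RING_ATOMS)  # O4', C1', C2', C3', C4'
    nus = []
    for j in range(5):
        quad = [ring[(j - 1) % 5], ring[j % 5], ring[(j + 1) % 5], ring[(j + 2) % 5]]
        nus.append(dihedral_from_coords(*(coords[a] for a in quad)))
    return RingTorsions(*nus)
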