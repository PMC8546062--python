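"""Candidate molecules, chemical-shift sets, and the predictor contract.

A candidate molecule carries an identifier and, optionally, a SMILES string
(opaque metadata — never parsed here) and a count of NMR-active atoms.  Its
chemical shifts come from a *predictor*: any callable with a ``label``
attribute that maps a :class:`Molecule` to a sequence of shift values in
ppm, or raises :class:`PredictionError`.  The bundled
:class:`TablePredictor` looks shifts up in a table, the same pathway as a
database of annotated shifts; empirical predictors (HOSE-code lookup,
graph neural networks, ...) plug in through the same contract.

Duplicate shift values are deliberately preserved: chemically equivalent
carbons legitimately resonate at the same frequency, and their lineshape
kernels must stack when the spectrum is estimated.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "Molecule",
    "ShiftSet",
    "Predictor",
    "PredictionError",
    "ShiftTableError",
    "TablePredictor",
    "predict_shifts",
    "load_shift_table",
    "write_shift_table",
    "load_pool",
    "write_pool",
    "PROVENANCE_ORDER",
]

#: canonical ordering of shift-set provenances, used for tie-breaking
PROVENANCE_ORDER = ("table", "hose", "mpnn", "other")


class PredictionError(Exception):
    """A predictor could not produce shifts for a molecule."""


class ShiftTableError(ValueError):
    """A shift table or pool file could not be parsed."""


@dataclasses.dataclass(frozen=True)
class Molecule:
    """A candidate molecule in the search pool."""

    id: str
    smiles: str | None = None
    n_active: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("molecule id must be nonempty")
        if self.n_active is not None and self.n_active < 1:
            raise ValueError("n_active must be >= 1 when present")


@dataclasses.dataclass(frozen=True)
class ShiftSet:
    """Predicted or annotated chemical shifts of one molecule.

    Shifts are stored sorted ascending (ties allowed for chemically
    equivalent atoms); the constructor sorts its input.
    """

    molecule_id: str
    shifts: np.ndarray
    provenance: str = "table"

    def __post_init__(self) -> None:
        s = np.sort(np.asarray(self.shifts, dtype=float))
        object.__setattr__(self, "shifts", s)
        if s.size < 1:
            raise ValueError(f"{self.molecule_id}: shift set must be nonempty")
        if not np.all(np.isfinite(s)):
            raise ValueError(f"{self.molecule_id}: shifts must be finite")

    @property
    def m(self) -> int:
        """Number of shifts (NMR-active atoms represented)."""
        return int(self.shifts.size)


@runtime_checkable
class Predictor(Protocol):
    """Contract for chemical-shift predictors."""

    label: str

    def __call__(self, molecule: Molecule) -> Sequence[float]: ...


@dataclasses.dataclass
class TablePredictor:
    """Predictor backed by a shift table keyed on molecule id.

    Raises :class:`PredictionError` for molecules absent from the table.
    """

    table: Mapping[str, Sequence[ShiftSet]]
    label: str = "table"

    def __call__(self, molecule: Molecule) -> Sequence[float]:
        sets = self.table.get(molecule.id)
        if not sets:
            raise PredictionError(f"no shifts tabulated for molecule {molecule.id!r}")
        for ss in sets:
            if ss.provenance == self.label:
                return ss.shifts
        return sets[0].shifts


def predict_shifts(molecule: Molecule, predictor: Predictor) -> ShiftSet:
    """Run a predictor and package its output as a sorted :class:`ShiftSet`.

    Predictor failures propagate as :class:`PredictionError`; downstream
    scoring treats the molecule as unpredictable (score -C), never as a
    hard error for the whole pool.
    """
    values = predictor(molecule)
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise PredictionError(f"predictor returned no shifts for {molecule.id!r}")
    label = getattr(predictor, "label", "other")
    return ShiftSet(molecule_id=molecule.id, shifts=values, provenance=label)


def _split_line(line: str) -> list[str]:
    delim = "," if "," in line else ("\t" if "\t" in line else None)
    parts = line.split(delim) if delim else line.split()
    return [p for p in (q.strip() for q in parts) if p]


def load_shift_table(path: str | Path) -> dict[str, list[ShiftSet]]:
    """Load a long-format shift table: molecule_id, shift_ppm[, provenance].

    Rows are grouped by (molecule_id, provenance); each group becomes one
    ascending :class:`ShiftSet`.  Duplicate rows are kept.  A single header
    line is tolerated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"shift table not found: {path}")
    groups: dict[tuple[str, str], list[float]] = {}
    n_rows = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = _split_line(line)
            if len(parts) < 2:
                raise ShiftTableError(
                    f"{path}:{lineno}: expected molecule_id and shift_ppm columns"
                )
            mol_id, shift_s = parts[0], parts[1]
            prov = parts[2] if len(parts) > 2 else "table"
            try:
                shift = float(shift_s)
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ShiftTableError(
                    f"{path}:{lineno}: non-numeric shift value {shift_s!r}"
                ) from None
            groups.setdefault((mol_id, prov), []).append(shift)
            n_rows += 1
    if n_rows == 0:
        raise ShiftTableError(f"{path}: empty shift table")
    table: dict[str, list[ShiftSet]] = {}
    for (mol_id, prov), values in groups.items():
        table.setdefault(mol_id, []).append(
            ShiftSet(molecule_id=mol_id, shifts=np.array(values), provenance=prov)
        )
    return table


def write_shift_table(table: Mapping[str, Sequence[ShiftSet]], path: str | Path) -> None:
    """Write a shift table in the long tab-separated format."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("molecule_id\tshift_ppm\tprovenance\n")
        for mol_id in table:
            for ss in table[mol_id]:
                for shift in ss.shifts:
                    fh.write(f"{mol_id}\t{shift:.6f}\t{ss.provenance}\n")


def load_pool(path: str | Path) -> dict[str, Molecule]:
    """Load a pool file: molecule_id[, smiles][, n_active]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pool file not found: {path}")
    pool: dict[str, Molecule] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = _split_line(line)
            if lineno == 1 and parts[0].lower() == "molecule_id":
                continue
            mol_id = parts[0]
            smiles = parts[1] if len(parts) > 1 and parts[1] != "-" else None
            n_active = None
            if len(parts) > 2:
                try:
                    n_active = int(parts[2])
                except ValueError:
                    raise ShiftTableError(
                        f"{path}:{lineno}: non-integer n_active {parts[2]!r}"
                    ) from None
            if mol_id in pool:
                raise ShiftTableError(f"{path}:{lineno}: duplicate molecule id {mol_id!r}")
            pool[mol_id] = Molecule(id=mol_id, smiles=smiles, n_active=n_active)
    if not pool:
        raise ShiftTableError(f"{path}: empty pool file")
    return pool


def write_pool(pool: Mapping[str, Molecule], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("molecule_id\tsmiles\tn_active\n")
        for mol in pool.values():
            smiles = mol.smiles if mol.smiles else "-"
            n_active = str(mol.n_active) if mol.n_active is not None else ""
            fh.write(f"{mol.id}\t{smiles}\t{n_active}\n")
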