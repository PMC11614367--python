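"""Dataset handling: molecules, curation rules, and frequency pairing.

A training set couples, per molecule, the experimental gas-phase fundamental
transition wavenumbers with harmonic wavenumbers computed by one or more
quantum-chemical methods.  Pairing is purely value-based: both lists are
sorted ascending and zipped index-wise.  A nonlinear N-atomic molecule
carries 3N-6 fundamentals (a diatomic carries one); a linear molecule has
3N-5 physical modes but the lowest-energy vibration — usually one component
of a doubly degenerate bend — is disregarded, so 3N-6 entries are retained
there too.

All wavenumbers are in cm^-1 throughout; there is no unit-conversion layer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyDatasetError,
    InvalidFrequencyError,
    InvalidMoleculeError,
    ModeCountMismatchError,
    SchemaError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Molecule",
    "FrequencyPair",
    "PairTable",
    "expected_mode_count",
    "validate_molecule",
    "pair_molecule",
    "build_pair_table",
    "load_dataset",
    "save_dataset",
    "pair_table_to_csv",
    "pair_table_from_csv",
    "validation_report",
]


@dataclass
class Molecule:
    """One molecule of the dataset.

    Parameters
    ----------
    id : str
        Unique text label (e.g. a CCCBDB-style formula or CAS name).
    formula : str
        Chemical formula, informational only.
    n_atoms : int
        Number of atoms, >= 2.
    is_linear : bool
        Whether the equilibrium geometry is linear (diatomics are).
    charge : int
        Net charge; the training-set curation rule expects 0.
    multiplicity : int
        Spin multiplicity; the curation rule expects 1 (singlet).
    exp_frequencies : list of float
        Experimental fundamental transition wavenumbers, cm^-1.
    calc_frequencies : dict of str -> list of float
        Computed harmonic wavenumbers keyed by method label.
    """

    id: str
    formula: str
    n_atoms: int
    is_linear: bool
    charge: int = 0
    multiplicity: int = 1
    exp_frequencies: list[float] = field(default_factory=list)
    calc_frequencies: dict[str, list[float]] = field(default_factory=dict)

    @property
    def methods(self) -> list[str]:
        return list(self.calc_frequencies)


@dataclass(frozen=True)
class FrequencyPair:
    """A single (computed, experimental) wavenumber pair in cm^-1."""

    nu_calc: float
    nu_exp: float
    molecule_id: str
    method: str


@dataclass
class PairTable:
    """Flat list of frequency pairs across molecules for one method.

    This is the direct input to scale-factor fitting; ``n_total`` is the
    total number of frequencies in the training set (the sum over molecules
    of their retained mode counts).
    """

    method: str
    pairs: list[FrequencyPair] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.pairs)

    @property
    def nu_calc(self) -> np.ndarray:
        return np.array([p.nu_calc for p in self.pairs], dtype=float)

    @property
    def nu_exp(self) -> np.ndarray:
        return np.array([p.nu_exp for p in self.pairs], dtype=float)

    def __len__(self) -> int:
        return len(self.pairs)


def expected_mode_count(n_atoms: int, is_linear: bool) -> int:
    """Number of retained vibrational entries for a molecule.

    Diatomics have a single vibration.  Larger molecules are characterised
    with 3N-6 fundamentals regardless of linearity: linear molecules have
    3N-5 physical modes, but the lowest-energy one (typically one component
    of a doubly degenerate bend) is disregarded, leaving 3N-6.

    Raises
    ------
    InvalidMoleculeError
        If ``n_atoms`` < 2.
    """
    if n_atoms < 2:
        raise InvalidMoleculeError(
            f"a molecule needs at least 2 atoms, got n_atoms={n_atoms}"
        )
    if n_atoms == 2:
        return 1
    return 3 * n_atoms - 6


def _effective_count(freqs: Sequence[float], expected: int, is_linear: bool) -> int:
    """Length of a frequency list after the prospective linear-molecule drop."""
    n = len(freqs)
    if is_linear and n == expected + 1:
        return n - 1
    return n


def validate_molecule(
    mol: Molecule, method: str, *, strict_curation: bool = False
) -> Molecule:
    """Validate one molecule for pairing with ``method``.

    Checks that all wavenumbers are strictly positive and that, after the
    linear-molecule drop rule is (prospectively) applied, both the
    experimental and computed lists have ``expected_mode_count`` entries.

    The training-set curation rules (neutral charge, singlet ground state)
    are warnings by default — they describe the published training set, not
    a constraint of the mathematics — and errors with ``strict_curation``.

    Returns the molecule unchanged.
    """
    if method not in mol.calc_frequencies:
        raise InvalidMoleculeError(
            f"molecule {mol.id!r} has no computed frequencies for method {method!r}"
        )
    expected = expected_mode_count(mol.n_atoms, mol.is_linear)

    for label, freqs in (
        ("experimental", mol.exp_frequencies),
        ("computed", mol.calc_frequencies[method]),
    ):
        for nu in freqs:
            if not nu > 0:
                raise InvalidFrequencyError(
                    f"molecule {mol.id!r}: non-positive {label} wavenumber {nu}"
                )

    if mol.charge != 0 or mol.multiplicity != 1:
        msg = (
            f"molecule {mol.id!r} violates the training-set curation rules "
            f"(charge={mol.charge}, multiplicity={mol.multiplicity}; "
            "expected a neutral singlet)"
        )
        if strict_curation:
            raise InvalidMoleculeError(msg)
        logger.warning(msg)

    n_exp = _effective_count(mol.exp_frequencies, expected, mol.is_linear)
    n_calc = _effective_count(mol.calc_frequencies[method], expected, mol.is_linear)
    if n_exp != expected or n_calc != expected:
        raise ModeCountMismatchError(
            f"molecule {mol.id!r}: expected {expected} modes "
            f"(n_atoms={mol.n_atoms}, linear={mol.is_linear}) but found "
            f"{len(mol.exp_frequencies)} experimental / "
            f"{len(mol.calc_frequencies[method])} computed entries, "
            "not resolvable by the linear-molecule drop rule"
        )
    return mol


def pair_molecule(
    mol: Molecule, method: str, *, strict_curation: bool = False
) -> list[FrequencyPair]:
    """Pair experimental and computed frequencies of one molecule.

    Both lists are sorted ascending (stable, so exactly degenerate entries
    keep input order) and zipped index-wise.  For a linear molecule whose
    list has exactly one entry more than the retained count, the single
    lowest value of that list is removed first; this is applied to either
    list independently, so a computed list with the extra bend component and
    an experimental list without it pair up correctly.
    """
    validate_molecule(mol, method, strict_curation=strict_curation)
    expected = expected_mode_count(mol.n_atoms, mol.is_linear)

    exp = sorted(mol.exp_frequencies)
    calc = sorted(mol.calc_frequencies[method])
    if mol.is_linear and len(calc) == expected + 1:
        dropped = calc.pop(0)
        logger.debug(
            "molecule %r: dropped lowest computed frequency %.2f cm^-1 "
            "(linear-molecule rule)", mol.id, dropped,
        )
    if mol.is_linear and len(exp) == expected + 1:
        dropped = exp.pop(0)
        logger.debug(
            "molecule %r: dropped lowest experimental frequency %.2f cm^-1 "
            "(linear-molecule rule)", mol.id, dropped,
        )
    return [
        FrequencyPair(nu_calc=c, nu_exp=e, molecule_id=mol.id, method=method)
        for c, e in zip(calc, exp)
    ]


def build_pair_table(
    dataset: Iterable[Molecule],
    method: str,
    *,
    lenient: bool = False,
    strict_curation: bool = False,
) -> PairTable:
    """Concatenate the pairs of all molecules into one fitting table.

    In strict mode (default) any molecule failing validation aborts the
    build; with ``lenient=True`` it is skipped with a logged warning.

    Raises
    ------
    EmptyDatasetError
        If no pairs result.
    """
    pairs: list[FrequencyPair] = []
    for mol in dataset:
        try:
            pairs.extend(pair_molecule(mol, method, strict_curation=strict_curation))
        except (InvalidMoleculeError, InvalidFrequencyError, ModeCountMismatchError):
            if lenient:
                logger.warning("skipping molecule %r (failed validation)", mol.id)
                continue
            raise
    if not pairs:
        raise EmptyDatasetError(f"no frequency pairs for method {method!r}")
    return PairTable(method=method, pairs=pairs)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = {
    "id": str,
    "formula": str,
    "n_atoms": int,
    "is_linear": bool,
    "charge": int,
    "multiplicity": int,
    "exp_frequencies": list,
    "calc_frequencies": dict,
}


def _molecule_from_record(rec: dict, index: int) -> Molecule:
    if not isinstance(rec, dict):
        raise SchemaError(f"molecules[{index}] is not an object")
    for key, typ in _REQUIRED_FIELDS.items():
        if key not in rec:
            raise SchemaError(f"molecules[{index}] is missing field {key!r}")
        if typ in (int,) and isinstance(rec[key], bool):
            raise SchemaError(f"molecules[{index}].{key} must be an integer")
        if not isinstance(rec[key], typ):
            raise SchemaError(
                f"molecules[{index}].{key} must be of type {typ.__name__}"
            )
    exp = [float(v) for v in rec["exp_frequencies"]]
    calc = {}
    for meth, freqs in rec["calc_frequencies"].items():
        if not isinstance(freqs, list):
            raise SchemaError(
                f"molecules[{index}].calc_frequencies[{meth!r}] must be a list"
            )
        calc[str(meth)] = [float(v) for v in freqs]
    return Molecule(
        id=rec["id"],
        formula=rec["formula"],
        n_atoms=rec["n_atoms"],
        is_linear=rec["is_linear"],
        charge=rec["charge"],
        multiplicity=rec["multiplicity"],
        exp_frequencies=exp,
        calc_frequencies=calc,
    )


def load_dataset(path: str | Path) -> list[Molecule]:
    """Load a dataset JSON file (see schemas/dataset.schema.json)."""
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "molecules" not in doc:
        raise SchemaError(f"{path}: top level must be an object with 'molecules'")
    if not isinstance(doc["molecules"], list):
        raise SchemaError(f"{path}: 'molecules' must be a list")
    return [_molecule_from_record(rec, i) for i, rec in enumerate(doc["molecules"])]


def save_dataset(dataset: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules to the dataset JSON layout."""
    doc = {
        "molecules": [
            {
                "id": m.id,
                "formula": m.formula,
                "n_atoms": m.n_atoms,
                "is_linear": m.is_linear,
                "charge": m.charge,
                "multiplicity": m.multiplicity,
                "exp_frequencies": list(m.exp_frequencies),
                "calc_frequencies": {k: list(v) for k, v in m.calc_frequencies.items()},
            }
            for m in dataset
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def pair_table_to_csv(table: PairTable, path: str | Path) -> None:
    """Export a pair table as CSV: molecule_id,method,nu_calc,nu_exp."""
    df = pd.DataFrame(
        {
            "molecule_id": [p.molecule_id for p in table.pairs],
            "method": [p.method for p in table.pairs],
            "nu_calc": [p.nu_calc for p in table.pairs],
            "nu_exp": [p.nu_exp for p in table.pairs],
        }
    )
    df.to_csv(path, index=False)


def pair_table_from_csv(path: str | Path) -> PairTable:
    """Read a pair table from the CSV layout written by pair_table_to_csv."""
    df = pd.read_csv(path)
    missing = {"molecule_id", "method", "nu_calc", "nu_exp"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise EmptyDatasetError(f"{path}: no pairs")
    methods = df["method"].unique()
    if len(methods) > 1:
        raise SchemaError(f"{path}: more than one method label: {list(methods)}")
    pairs = [
        FrequencyPair(
            nu_calc=float(r.nu_calc),
            nu_exp=float(r.nu_exp),
            molecule_id=str(r.molecule_id),
            method=str(r.method),
        )
        for r in df.itertuples()
    ]
    return PairTable(method=str(methods[0]), pairs=pairs)


def validation_report(dataset: Iterable[Molecule], method: str) -> str:
    """Plain-text per-molecule validation status for one method."""
    lines = []
    n_ok = 0
    dataset = list(dataset)
    for mol in dataset:
        try:
            pairs = pair_molecule(mol, method)
        except (InvalidMoleculeError, InvalidFrequencyError,
                ModeCountMismatchError) as exc:
            lines.append(f"{mol.id}: INVALID — {exc}")
            continue
        n_ok += 1
        note = ""
        expected = expected_mode_count(mol.n_atoms, mol.is_linear)
        if mol.is_linear and len(mol.calc_frequencies[method]) == expected + 1:
            note = " (lowest computed frequency dropped: linear-molecule rule)"
        lines.append(f"{mol.id}: ok, {len(pairs)} pairs{note}")
    lines.append(f"-- {n_ok}/{len(dataset)} molecules valid for method {method!r}")
    return "\n".join(lines)
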