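"""Registry of amino-acid property tables used for residue encoding.

Sixteen sequence-level indices are bundled as versioned data files (one
table per file, ``#name`` / ``#units`` / ``#source`` header lines followed by
20 residue/value rows):

* ``HP`` Kyte-Doolittle hydropathy
* ``Mw`` free-amino-acid molecular mass
* ``IP`` isoelectric point
* ``pa``, ``pb``, ``pt`` Levitt helix/sheet/turn preferences
* ``Z1``, ``Z2``, ``Z3`` Hellberg-Wold principal property scores
* ``ECI`` electronic charge index, ``ISA`` isotropic surface area
* ``Ap`` polar surface area (synthetic stand-in table)
* ``dGsU`` superficial free energy, computed at load time as the product of
  the Kyte-Doolittle hydropathy and the residue's total accessible surface
  area (auxiliary ``SA`` table)
* ``dHf`` nonapeptide formation enthalpy (synthetic stand-in table)
* ``L19``, ``Xi`` sequence-compatibility parameters (synthetic stand-in
  tables)

Files whose names contain ``.synthetic`` hold constructed stand-in values,
documented as such in their ``#source`` line; the remaining tables are
transcribed from the literature sources recorded there.  Custom tables can
shadow bundled ones via :func:`load_custom_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .seq_io import AMINO_ACIDS

_DATA_PACKAGE = "afseq.data.aa_indices"

#: Codes of the 16 sequence-level indices available by default.
INDEX_CODES = (
    "HP", "Mw", "IP", "pa", "pb", "pt", "Z1", "Z2", "Z3",
    "ECI", "ISA", "Ap", "dGsU", "dHf", "L19", "Xi",
)


@dataclass(frozen=True)
class AAIndexTable:
    """A named mapping from the 20 standard residues to real values."""

    name: str
    values: dict[str, float]
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        missing = sorted(set(AMINO_ACIDS) - set(self.values))
        if missing:
            raise ValueError(f"table {self.name!r}: missing residue {missing[0]}")
        extra = sorted(set(self.values) - set(AMINO_ACIDS))
        if extra:
            raise ValueError(f"table {self.name!r}: unknown residue {extra[0]!r}")
        for res, val in self.values.items():
            if not math.isfinite(val):
                raise ValueError(f"table {self.name!r}: non-finite value for {res}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def as_vector(self) -> np.ndarray:
        """Values ordered by :data:`afseq.seq_io.AMINO_ACIDS`."""
        return np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)

    def scaled(self, c: float, name: str | None = None) -> "AAIndexTable":
        return AAIndexTable(
            name=name or f"{self.name}x{c:g}",
            values={k: v * c for k, v in self.values.items()},
            units=self.units,
            source=f"{self.source} (rescaled by {c:g})",
        )


def _parse_table(text: str, origin: str) -> AAIndexTable:
    name = ""
    units = ""
    source = ""
    values: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("#name"):
            name = line.split(None, 1)[1].strip()
        elif line.startswith("#units"):
            units = line.split(None, 1)[1].strip() if " " in line else ""
        elif line.startswith("#source"):
            source = line.split(None, 1)[1].strip() if " " in line else ""
        elif line.startswith("#"):
            continue
        else:
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{origin}:{lineno}: expected '<residue>\\t<value>'")
            res = parts[0].strip().upper()
            if res in values:
                raise ValueError(f"{origin}:{lineno}: duplicate residue {res}")
            try:
                values[res] = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{origin}:{lineno}: non-numeric value {parts[1]!r}") from exc
    if not name:
        raise ValueError(f"{origin}: missing '#name <code>' line")
    return AAIndexTable(name=name, values=values, units=units, source=source)


def _read_bundled(code: str) -> AAIndexTable:
    root = resources.files(_DATA_PACKAGE)
    for fname in (f"{code}.tsv", f"{code}.synthetic.tsv"):
        candidate = root.joinpath(fname)
        if candidate.is_file():
            return _parse_table(candidate.read_text(), fname)
    raise KeyError(code)


class IndexRegistry:
    """Lazily loaded registry of bundled and user-registered tables."""

    def __init__(self) -> None:
        self._tables: dict[str, AAIndexTable] = {}

    def get(self, name: str) -> AAIndexTable:
        if name in self._tables:
            return self._tables[name]
        if name == "dGsU":
            table = self._build_dgsu()
        else:
            try:
                table = _read_bundled(name)
            except KeyError:
                raise KeyError(
                    f"unknown index {name!r}; available: {', '.join(self.available())}"
                ) from None
        self._tables[name] = table
        return table

    def _build_dgsu(self) -> AAIndexTable:
        hp = self.get("HP")
        sa = _read_bundled("SA")
        values = {a: hp[a] * sa[a] for a in AMINO_ACIDS}
        return AAIndexTable(
            name="dGsU",
            values=values,
            units="A^2 * hydropathy (superficial free energy)",
            source=(
                "computed: Kyte-Doolittle hydropathy (HP) x total accessible "
                f"surface area ({sa.source})"
            ),
        )

    def register(self, table: AAIndexTable) -> None:
        """Register (or shadow) a table under its own name."""
        self._tables[table.name] = table

    def available(self) -> list[str]:
        extra = sorted(set(self._tables) - set(INDEX_CODES))
        return list(INDEX_CODES) + extra


_REGISTRY = IndexRegistry()


def get_index(name: str) -> AAIndexTable:
    """Return the registered table for ``name`` (bundled or custom)."""
    return _REGISTRY.get(name)


def register_index(table: AAIndexTable) -> None:
    """Register a table object, shadowing any bundled table of that name."""
    _REGISTRY.register(table)


def load_custom_table(path: str | Path) -> AAIndexTable:
    """Load a user table file and register it.

    Format: line 1 ``#name <code>``, then 20 lines ``<residue>\\t<value>``;
    optional ``#units`` / ``#source`` comment lines.
    """
    path = Path(path)
    table = _parse_table(path.read_text(), str(path))
    _REGISTRY.register(table)
    return table
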