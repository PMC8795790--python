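"""Amino-acid descriptor (AAD) tables and the table registry.

An AAD table maps each of the 20 standard residues to a fixed-length numeric
vector (e.g. VHSE's eight principal-property scores).  Peptide sequences are
encoded positionwise by substituting each residue with its vector, so the
table is the single source of truth for the descriptor dimension ``m``.

Four tables ship with the package: VHSE (physicochemical, from the published
scale) and MolSurf / ST_scale / VSGETAWAY, which are synthetic stand-ins
built from classical residue property scales (see the packaged CSV headers).
User tables can be registered at run time under any unused name.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: one-letter codes of the 20 standard residues, fixed order
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: coarse property families used to label tables
PROPERTY_CLASSES = (
    "quantum-chemical",
    "topological",
    "physicochemical",
    "3D-structural",
    "other",
)

#: nonstandard code -> parent standard residue (phospho-serine/-threonine)
PARENT_RESIDUE = {"s": "S", "t": "T"}

_EXTENSION_PREFIX = "#extension:"


class AADError(ValueError):
    """Raised for malformed descriptor tables or unresolvable residues."""


@dataclass(frozen=True)
class AADTable:
    """A named 20-residue descriptor table of dimension ``m``.

    ``values`` maps each standard one-letter code to an ``m``-vector;
    ``extensions`` optionally carries dedicated vectors for nonstandard
    codes (e.g. ``'s'`` for phospho-serine).
    """

    name: str
    property_class: str
    m: int
    values: Mapping[str, tuple]
    source: str = ""
    extensions: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        if self.m < 1:
            raise AADError(f"descriptor dimension must be >= 1, got {self.m}")
        if self.property_class not in PROPERTY_CLASSES:
            raise AADError(
                f"unknown property class {self.property_class!r}; "
                f"expected one of {PROPERTY_CLASSES}"
            )
        missing = [r for r in STANDARD_RESIDUES if r not in self.values]
        if missing:
            raise AADError(
                f"incomplete alphabet in table {self.name!r}: "
                f"missing residue(s) {', '.join(missing)}"
            )
        extra = [r for r in self.values if r not in STANDARD_RESIDUES]
        if extra:
            raise AADError(
                f"non-standard code(s) {extra} in table {self.name!r}; "
                "declare them in the extension block instead"
            )
        for code, vec in list(self.values.items()) + list(self.extensions.items()):
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (self.m,):
                raise AADError(
                    f"residue {code!r} in table {self.name!r} has "
                    f"{arr.size} components, expected m={self.m}"
                )
            if not np.all(np.isfinite(arr)):
                raise AADError(
                    f"non-finite descriptor value for residue {code!r} "
                    f"in table {self.name!r}"
                )

    @property
    def alphabet(self) -> frozenset:
        """All codes this table can encode directly."""
        return frozenset(self.values) | frozenset(self.extensions)

    def vector(self, code: str, policy: str = "parent_residue") -> np.ndarray:
        """Descriptor vector for one residue code.

        ``policy`` controls nonstandard codes without a dedicated extension
        vector: ``"parent_residue"`` maps phospho codes ('s', 't') to their
        parent residue with a logged warning; ``"strict"`` raises.
        """
        if code in self.values:
            return np.asarray(self.values[code], dtype=float)
        if code in self.extensions:
            return np.asarray(self.extensions[code], dtype=float)
        if policy == "parent_residue" and code in PARENT_RESIDUE:
            parent = PARENT_RESIDUE[code]
            logger.warning(
                "table %s has no vector for phospho code %r; "
                "using parent residue %r",
                self.name, code, parent,
            )
            return np.asarray(self.values[parent], dtype=float)
        raise AADError(f"unresolvable residue {code!r} under table {self.name!r}")

    def to_matrix(self) -> np.ndarray:
        """20 x m array in STANDARD_RESIDUES order."""
        return np.array([self.values[r] for r in STANDARD_RESIDUES], dtype=float)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def _parse_rows(lines, name_hint):
    meta = {"name": name_hint, "property_class": "other", "source": ""}
    values: dict[str, tuple] = {}
    extensions: dict[str, tuple] = {}
    header = None
    m = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#") and not line.startswith(_EXTENSION_PREFIX):
            # metadata comments: "# key: value"
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip()
                if key in meta:
                    meta[key] = val.strip()
            continue
        fields = next(csv.reader([line]))
        if header is None:
            header = fields
            if len(header) < 2 or header[0].strip().lower() != "residue":
                raise AADError(
                    "descriptor table must start with a header "
                    "'residue,c1,...,cm'"
                )
            m = len(header) - 1
            continue
        code = fields[0].strip()
        is_ext = code.startswith(_EXTENSION_PREFIX)
        if is_ext:
            code = code[len(_EXTENSION_PREFIX):].strip()
        if len(fields) - 1 != m:
            raise AADError(
                f"row {lineno} ({code!r}): expected {m} components, "
                f"got {len(fields) - 1}"
            )
        vec = []
        for j, cell in enumerate(fields[1:], start=1):
            try:
                vec.append(float(cell))
            except ValueError:
                raise AADError(
                    f"non-numeric descriptor value at row {lineno}, "
                    f"column {header[j]}: {cell!r}"
                ) from None
        target = extensions if is_ext else values
        if code in target:
            raise AADError(f"duplicate residue {code!r} at row {lineno}")
        target[code] = tuple(vec)
    if header is None:
        raise AADError("empty descriptor table")
    return meta, m, values, extensions


def load_aad_table(source, name: str | None = None) -> AADTable:
    """Load a descriptor table from a CSV file.

    The file dialect is ``residue,c1,...,cm`` with a header row, exactly the
    20 standard-residue data rows, optional ``#extension:<code>`` rows for
    nonstandard codes, and optional ``# key: value`` metadata comments
    (keys: name, property_class, source).  ``m`` is inferred from the
    column count.
    """
    path = Path(source)
    with open(path, newline="") as fh:
        meta, m, values, extensions = _parse_rows(fh, path.stem)
    if name is not None:
        meta["name"] = name
    return AADTable(
        name=meta["name"],
        property_class=meta["property_class"],
        m=m,
        values=values,
        source=meta["source"],
        extensions=extensions,
    )


def write_aad_table(table: AADTable, path) -> None:
    """Write a table in the CSV dialect accepted by :func:`load_aad_table`."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# name: {table.name}\n")
        fh.write(f"# property_class: {table.property_class}\n")
        if table.source:
            fh.write(f"# source: {table.source}\n")
        fh.write("residue," + ",".join(f"c{i + 1}" for i in range(table.m)) + "\n")
        for code in STANDARD_RESIDUES:
            vals = ",".join(repr(float(v)) for v in table.values[code])
            fh.write(f"{code},{vals}\n")
        for code, vec in table.extensions.items():
            vals = ",".join(repr(float(v)) for v in vec)
            fh.write(f"{_EXTENSION_PREFIX}{code},{vals}\n")


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_PACKAGED_FILES = {
    "MolSurf": "MolSurf.synthetic.csv",
    "ST_scale": "ST_scale.synthetic.csv",
    "VHSE": "VHSE.csv",
    "VSGETAWAY": "VSGETAWAY.synthetic.csv",
}

_registry: dict[str, AADTable] = {}
_packaged_loaded = False


def _ensure_packaged() -> None:
    global _packaged_loaded
    if _packaged_loaded:
        return
    base = resources.files("pqsar").joinpath("data", "aad")
    for name, fname in _PACKAGED_FILES.items():
        with resources.as_file(base.joinpath(fname)) as path:
            _registry.setdefault(name, load_aad_table(path, name=name))
    _packaged_loaded = True


def register_table(table: AADTable, overwrite: bool = False) -> None:
    """Add a table to the registry; name collisions raise unless allowed."""
    _ensure_packaged()
    if table.name in _registry and not overwrite:
        raise AADError(f"a table named {table.name!r} is already registered")
    _registry[table.name] = table


def get_table(name: str) -> AADTable:
    _ensure_packaged()
    try:
        return _registry[name]
    except KeyError:
        raise AADError(
            f"no registered descriptor table named {name!r}; "
            f"available: {', '.join(list_tables())}"
        ) from None


def list_tables() -> list[str]:
    """Registered table names, packaged tables first, then registration order."""
    _ensure_packaged()
    return list(_registry)


def decorrelated_table(base: str = "VHSE", name: str | None = None) -> AADTable:
    """A variant of ``base`` whose columns are orthonormal over the alphabet.

    The 20 x m descriptor matrix is column-centered and PCA-whitened over
    the residue rows, so over a uniform residue draw the new components are
    exactly uncorrelated with unit variance.  Useful when a planted linear
    signal should be fully recoverable without collinearity losses.
    """
    table = get_table(base)
    M = table.to_matrix()
    Mc = M - M.mean(axis=0)
    U, S, _ = np.linalg.svd(Mc, full_matrices=False)
    keep = S > 1e-10 * S[0]
    W = U[:, keep] * np.sqrt(M.shape[0])
    values = {r: tuple(W[i]) for i, r in enumerate(STANDARD_RESIDUES)}
    return AADTable(
        name=name or f"{base}_ortho",
        property_class=table.property_class,
        m=int(keep.sum()),
        values=values,
        source=f"PCA-whitened over the residue alphabet from {base}",
    )
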