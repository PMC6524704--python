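"""Physicochemical description of peptide sequences.

Each peptide is summarized by nine descriptors: length, GRAVY (mean
Kyte-Doolittle hydropathy), bulkiness (mean Zimmerman side-chain
cross-section, A^2), polarity (mean Grantham polarity), net charge at the
analysis pH (Henderson-Hasselbalch), and the proportions of basic (K, R, H),
acidic (D, E), aromatic (F, W, Y) and proline residues.

All nine descriptors are composition-based: permuting residues never
changes them. Scales and pKa values ship as plain-text tables under
``pepkin/data`` and can be replaced by user-supplied files.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "AMINO_ACIDS",
    "InvalidSequenceError",
    "ScaleTable",
    "PkaSet",
    "PropertyVector",
    "PropertyConfig",
    "KYTE_DOOLITTLE",
    "ZIMMERMAN",
    "GRANTHAM",
    "EMBOSS_PKA",
    "clean_sequence",
    "validate_sequence",
    "compute_gravy",
    "compute_bulkiness",
    "compute_polarity",
    "compute_net_charge",
    "compute_residue_fractions",
    "compute_property_vector",
]

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)

BASIC_RESIDUES = frozenset("KRH")
ACIDIC_RESIDUES = frozenset("DE")
AROMATIC_RESIDUES = frozenset("FWY")


class InvalidSequenceError(ValueError):
    """A sequence contains a character outside the 20 standard residues."""

    def __init__(self, sequence: str, position: int, character: str):
        self.sequence = sequence
        self.position = position
        self.character = character
        super().__init__(
            f"invalid residue {character!r} at position {position + 1} "
            f"in sequence {sequence!r}"
        )


def clean_sequence(raw: str) -> str:
    """Strip modification annotations from an identification-output sequence.

    Search engines report variable modifications inline, e.g. ``M(ox)``,
    ``M[+15.99]`` or lowercase modified residues. Only the plain residue is
    scored, so bracketed annotations are removed and the sequence is
    uppercased. Whitespace is discarded.
    """
    out: list[str] = []
    depth = 0
    for ch in raw:
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth = max(0, depth - 1)
        elif depth == 0 and not ch.isspace():
            out.append(ch.upper())
    return "".join(out)


def validate_sequence(seq: str) -> str:
    """Return *seq* unchanged, or raise :class:`InvalidSequenceError`."""
    if len(seq) == 0:
        raise InvalidSequenceError(seq, 0, "")
    for i, ch in enumerate(seq):
        if ch not in _AA_SET:
            raise InvalidSequenceError(seq, i, ch)
    return seq


# ---------------------------------------------------------------------------
# Scale and pKa tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaleTable:
    """A per-residue numerical scale (one value for each of the 20 residues)."""

    name: str
    values: Mapping[str, float]
    citation: str = ""

    def __post_init__(self) -> None:
        missing = _AA_SET - set(self.values)
        extra = set(self.values) - _AA_SET
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    @classmethod
    def from_file(cls, path, name: str = "", citation: str = "") -> "ScaleTable":
        """Read a two-column (residue, value) table; ``#`` starts a comment."""
        values: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                residue, value = line.split()
                values[residue.upper()] = float(value)
        return cls(name=name or str(path), values=values, citation=citation)


@dataclass(frozen=True)
class PkaSet:
    """Ionizable-group pKa values for Henderson-Hasselbalch net charge.

    Acidic groups (side chains of D, E, C, Y and the carboxy terminus)
    contribute ``-1 / (1 + 10**(pKa - pH))``; basic groups (H, K, R side
    chains and the amino terminus) contribute ``+1 / (1 + 10**(pH - pKa))``.
    """

    acidic: Mapping[str, float]
    basic: Mapping[str, float]
    n_term: float
    c_term: float

    def __post_init__(self) -> None:
        for value in (*self.acidic.values(), *self.basic.values(),
                      self.n_term, self.c_term):
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa {value} outside (0, 14)")

    @classmethod
    def from_file(cls, path) -> "PkaSet":
        entries: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, value = line.split()
                entries[key] = float(value)
        acidic = {r: entries[r] for r in "DECY" if r in entries}
        basic = {r: entries[r] for r in "HKR" if r in entries}
        return cls(acidic=acidic, basic=basic,
                   n_term=entries["Nterm"], c_term=entries["Cterm"])


def _data_path(filename: str):
    return importlib.resources.files("pepkin.data").joinpath(filename)


KYTE_DOOLITTLE = ScaleTable.from_file(
    _data_path("hydropathy_kyte_doolittle.txt"),
    name="kyte_doolittle_hydropathy",
    citation="Kyte & Doolittle (1982) J Mol Biol 157:105-132",
)
ZIMMERMAN = ScaleTable.from_file(
    _data_path("bulkiness_zimmerman.txt"),
    name="zimmerman_bulkiness",
    citation="Zimmerman, Eliezer & Simha (1968) J Theor Biol 21:170-201",
)
GRANTHAM = ScaleTable.from_file(
    _data_path("polarity_grantham.txt"),
    name="grantham_polarity",
    citation="Grantham (1974) Science 185:862-864",
)
EMBOSS_PKA = PkaSet.from_file(_data_path("pka_emboss.txt"))


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

#: Descriptor names in canonical (barcode) order.
DESCRIPTOR_ORDER = (
    "length",
    "gravy",
    "bulkiness",
    "polarity",
    "net_charge",
    "frac_basic",
    "frac_acidic",
    "frac_aromatic",
    "frac_proline",
)


@dataclass(frozen=True)
class PropertyVector:
    """The nine physicochemical descriptors of one peptide."""

    length: int
    gravy: float
    bulkiness: float
    polarity: float
    net_charge: float
    frac_basic: float
    frac_acidic: float
    frac_aromatic: float
    frac_proline: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DESCRIPTOR_ORDER}


@dataclass(frozen=True)
class PropertyConfig:
    """Scales, pKa set and pH used for descriptor computation."""

    hydropathy: ScaleTable = KYTE_DOOLITTLE
    bulkiness: ScaleTable = ZIMMERMAN
    polarity: ScaleTable = GRANTHAM
    pka: PkaSet = EMBOSS_PKA
    ph: float = 6.0
    include_termini: bool = True


DEFAULT_CONFIG = PropertyConfig()


def _mean_scale(seq: str, scale: ScaleTable) -> float:
    validate_sequence(seq)
    return sum(scale.values[r] for r in seq) / len(seq)


def compute_gravy(seq: str, scale: ScaleTable = KYTE_DOOLITTLE) -> float:
    """Grand average of hydropathy: mean per-residue hydropathy value."""
    return _mean_scale(seq, scale)


def compute_bulkiness(seq: str, scale: ScaleTable = ZIMMERMAN) -> float:
    """Mean side-chain cross-section (A^2)."""
    return _mean_scale(seq, scale)


def compute_polarity(seq: str, scale: ScaleTable = GRANTHAM) -> float:
    """Mean Grantham polarity."""
    return _mean_scale(seq, scale)


def compute_net_charge(
    seq: str,
    ph: float = 6.0,
    pka: PkaSet = EMBOSS_PKA,
    include_termini: bool = True,
) -> float:
    """Henderson-Hasselbalch net charge at *ph*, in elementary charges.

    This is the raw (not length-normalized) sum over ionizable groups.
    Termini are included by default; at pH 6 the amino- and
    carboxy-terminus contributions nearly cancel.
    """
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH {ph} outside (0, 14)")
    validate_sequence(seq)
    charge = 0.0
    if include_termini:
        charge += 1.0 / (1.0 + 10.0 ** (ph - pka.n_term))
        charge -= 1.0 / (1.0 + 10.0 ** (pka.c_term - ph))
    for residue in seq:
        if residue in pka.basic:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka.basic[residue]))
        elif residue in pka.acidic:
            charge -= 1.0 / (1.0 + 10.0 ** (pka.acidic[residue] - ph))
    return charge


def compute_residue_fractions(seq: str) -> tuple[float, float, float, float]:
    """Proportions of basic, acidic, aromatic and proline residues."""
    validate_sequence(seq)
    n = len(seq)
    basic = sum(seq.count(r) for r in "KRH")
    acidic = sum(seq.count(r) for r in "DE")
    aromatic = sum(seq.count(r) for r in "FWY")
    proline = seq.count("P")
    return basic / n, acidic / n, aromatic / n, proline / n


def compute_property_vector(
    seq: str, config: PropertyConfig = DEFAULT_CONFIG
) -> PropertyVector:
    """All nine descriptors of *seq* in one pass. Deterministic."""
    validate_sequence(seq)
    frac_basic, frac_acidic, frac_aromatic, frac_proline = (
        compute_residue_fractions(seq)
    )
    return PropertyVector(
        length=len(seq),
        gravy=compute_gravy(seq, config.hydropathy),
        bulkiness=compute_bulkiness(seq, config.bulkiness),
        polarity=compute_polarity(seq, config.polarity),
        net_charge=compute_net_charge(
            seq, config.ph, config.pka, config.include_termini
        ),
        frac_basic=frac_basic,
        frac_acidic=frac_acidic,
        frac_aromatic=frac_aromatic,
        frac_proline=frac_proline,
    )
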