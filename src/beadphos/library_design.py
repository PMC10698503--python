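"""Phosphopeptide library representation and combinatorial expansion.

A library couples every synthesized peptide to a unique spectral code
(1:1 code ↔ sequence linkage).  Sequences use a canonical text notation in
which phosphorylated residues are written as lowercase ``s``/``t``/``y``
("LGAKKKtPLAAVSA" carries phospho-Thr at position 7).  Two other common
notations — a ``pS`` prefix ("LGAKKK(pT)PLAAVSA" or "...pT...") and the
``S(ph)`` suffix — are accepted on read and converted to the canonical form.

Positions are 1-based throughout, matching protein-residue convention.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import AmbiguityError, ConfigurationError, DuplicateSequenceError, InputError

#: Marker used for plus1_residue when the phospho residue is C-terminal.
TERMINAL = "*"

PHOSPHO_ACCEPTORS = "STY"

_PH_SUFFIX = re.compile(r"([STY])\(ph\)", re.IGNORECASE)
_P_PREFIX = re.compile(r"\(?p([STY])\)?")


def parse_sequence(text: str) -> tuple[str, frozenset[int]]:
    """Parse a peptide string in any accepted phospho notation.

    Returns ``(plain_sequence_upper, phospho_positions)`` with 1-based
    positions.  Accepted notations: lowercase s/t/y (canonical), ``pS`` /
    ``(pS)`` prefix, and ``S(ph)`` suffix.
    """
    text = text.strip()
    text = _PH_SUFFIX.sub(lambda m: m.group(1).lower(), text)
    text = _P_PREFIX.sub(lambda m: m.group(1).lower(), text)
    positions = set()
    plain = []
    for ch in text:
        if not ch.isalpha():
            raise InputError(f"unexpected character {ch!r} in sequence {text!r}")
        if ch.islower():
            if ch.upper() not in PHOSPHO_ACCEPTORS:
                raise InputError(f"phospho mark on non-acceptor residue {ch!r}")
            positions.add(len(plain) + 1)
        plain.append(ch.upper())
    return "".join(plain), frozenset(positions)


def to_canonical(sequence: str, phospho_positions) -> str:
    """Render a plain sequence plus positions in canonical lowercase notation."""
    chars = list(sequence.upper())
    for pos in phospho_positions:
        if not 1 <= pos <= len(chars):
            raise InputError(f"phospho position {pos} outside sequence of length {len(chars)}")
        if chars[pos - 1] not in PHOSPHO_ACCEPTORS:
            raise InputError(
                f"phospho position {pos} is {chars[pos - 1]}, not one of {PHOSPHO_ACCEPTORS}"
            )
        chars[pos - 1] = chars[pos - 1].lower()
    return "".join(chars)


@dataclass(frozen=True)
class PhosphoPeptide:
    """One library member with its design annotations.

    ``sequence`` is stored plain (uppercase); phospho state lives in
    ``phospho_positions``.  ``acceptor`` is "pS", "pT" or "none";
    ``plus1_residue`` is the residue immediately C-terminal of the (single)
    phospho position, or :data:`TERMINAL`.
    """

    peptide_id: str
    sequence: str
    phospho_positions: frozenset = field(default_factory=frozenset)
    code_id: str = ""
    acceptor: str = "none"
    plus1_residue: str = ""

    def __post_init__(self):
        for pos in self.phospho_positions:
            if not 1 <= pos <= len(self.sequence):
                raise InputError(f"{self.peptide_id}: phospho position {pos} out of range")
            if self.sequence[pos - 1] not in PHOSPHO_ACCEPTORS:
                raise InputError(
                    f"{self.peptide_id}: position {pos} is "
                    f"{self.sequence[pos - 1]}, not a phospho acceptor"
                )
        if len(self.phospho_positions) == 1:
            (pos,) = self.phospho_positions
            expected = "p" + self.sequence[pos - 1]
            if self.acceptor not in ("none", expected):
                raise InputError(
                    f"{self.peptide_id}: acceptor {self.acceptor} inconsistent with "
                    f"residue {self.sequence[pos - 1]} at position {pos}"
                )

    @property
    def canonical(self) -> str:
        return to_canonical(self.sequence, self.phospho_positions)

    @property
    def is_phosphorylated(self) -> bool:
        return bool(self.phospho_positions)


def annotate_peptide(p: PhosphoPeptide, primary_position: int | None = None) -> PhosphoPeptide:
    """Fill ``acceptor`` and ``plus1_residue`` from the phospho position.

    Multi-phospho peptides require ``primary_position`` to disambiguate.
    Unphosphorylated peptides get acceptor "none" and empty plus1.
    """
    if not p.phospho_positions:
        return replace(p, acceptor="none", plus1_residue="")
    if len(p.phospho_positions) > 1:
        if primary_position is None:
            raise AmbiguityError(
                f"{p.peptide_id}: multiple phospho positions "
                f"{sorted(p.phospho_positions)}; designate a primary position"
            )
        if primary_position not in p.phospho_positions:
            raise InputError(f"{p.peptide_id}: {primary_position} is not a phospho position")
        pos = primary_position
    else:
        (pos,) = p.phospho_positions
    acceptor = "p" + p.sequence[pos - 1]
    plus1 = p.sequence[pos] if pos < len(p.sequence) else TERMINAL
    return replace(p, acceptor=acceptor, plus1_residue=plus1)


@dataclass
class LibrarySpec:
    """Combinatorial design of a peptide panel.

    ``template`` uses ``Z`` for the single phospho-acceptor slot and ``X``
    for variant positions.  ``residue_sets`` maps each 1-based X position to
    its allowed residues; ``plus1_options``, if given, supplies the residue
    set for the X immediately after Z (overriding ``residue_sets``).
    """

    template: str
    residue_sets: dict = field(default_factory=dict)
    acceptor_options: tuple = ("pS", "pT")
    plus1_options: str | None = None

    def __post_init__(self):
        if self.template.count("Z") != 1:
            raise ConfigurationError("template must contain exactly one acceptor slot 'Z'")
        for acc in self.acceptor_options:
            if acc not in ("pS", "pT"):
                raise ConfigurationError(f"invalid acceptor option {acc!r}")

    @property
    def acceptor_slot(self) -> int:
        return self.template.index("Z") + 1

    def variant_positions(self) -> list[int]:
        return [i + 1 for i, ch in enumerate(self.template) if ch == "X"]

    def options_at(self, pos: int) -> str:
        if self.plus1_options is not None and pos == self.acceptor_slot + 1:
            return self.plus1_options
        try:
            return self.residue_sets[pos]
        except KeyError:
            raise ConfigurationError(
                f"template placeholder X at position {pos} has no residue set"
            ) from None


def expand_library(spec: LibrarySpec, id_prefix: str = "pep", code_prefix: str = "code") -> list[PhosphoPeptide]:
    """Enumerate every peptide a :class:`LibrarySpec` describes.

    Ordering is deterministic: lexicographic over (variant residues in
    position order, acceptor option).  Duplicate expanded sequences raise
    :class:`DuplicateSequenceError` listing the collisions.
    """
    positions = spec.variant_positions()
    option_lists = [sorted(spec.options_at(pos)) for pos in positions]
    acceptors = list(spec.acceptor_options)

    peptides = []
    seen: dict[str, str] = {}
    duplicates = []
    counter = itertools.count(1)
    for combo in itertools.product(*option_lists):
        for acc in acceptors:
            chars = list(spec.template)
            for pos, res in zip(positions, combo):
                chars[pos - 1] = res
            chars[spec.acceptor_slot - 1] = acc[1]  # S or T
            seq = "".join(chars)
            idx = next(counter)
            pid = f"{id_prefix}{idx:03d}"
            pep = PhosphoPeptide(
                peptide_id=pid,
                sequence=seq,
                phospho_positions=frozenset({spec.acceptor_slot}),
                code_id=f"{code_prefix}{idx:03d}",
            )
            pep = annotate_peptide(pep)
            if pep.canonical in seen:
                duplicates.append((seen[pep.canonical], pid, pep.canonical))
            seen[pep.canonical] = pid
            peptides.append(pep)
    if duplicates:
        raise DuplicateSequenceError(duplicates)
    return peptides


# ---------------------------------------------------------------------------
# Default dephosphorylation panel
# ---------------------------------------------------------------------------

#: Template of the dephos panel: three variable upstream positions, the
#: phospho acceptor, a variable +1 residue, then a fixed C-terminal stalk.
DEPHOS_TEMPLATE = "LGAXXXZXLXXVSA"

# Inner enumeration order per upstream combination; interleaves acceptor and
# +1-proline so a cap of the form 4k+2 keeps both factors balanced.
_INNER_ORDER = [("pS", "P"), ("pT", "A"), ("pS", "A"), ("pT", "P")]


def build_dephos_panel(n_phospho: int = 94, control: bool = True) -> list[PhosphoPeptide]:
    """Generate the default dephosphorylation screening panel.

    ``n_phospho`` phosphopeptides vary three upstream residues (acidic /
    basic / small / hydrophobic), the phospho acceptor (pS or pT) and the +1
    residue (Pro or Ala), enumerated so that exactly half carry pT and half
    carry +1 Pro whenever ``n_phospho`` is a multiple of 2.  With
    ``control=True`` a phosphate-free peptide is appended as the negative
    control, giving ``n_phospho + 1`` entries.
    """
    upstream_sets = [sorted("ADK"), sorted("ADK"), sorted("ADKL")]

    peptides = []
    idx = 0
    for combo in itertools.product(*upstream_sets):
        for acc, plus1 in _INNER_ORDER:
            if idx >= n_phospho:
                break
            idx += 1
            chars = list(DEPHOS_TEMPLATE)
            chars[3], chars[4], chars[5] = combo
            chars[6] = acc[1]
            chars[7] = plus1
            chars[9], chars[10] = "A", "E"
            seq = "".join(chars)
            pep = PhosphoPeptide(
                peptide_id=f"pep{idx:03d}",
                sequence=seq,
                phospho_positions=frozenset({7}),
                code_id=f"code{idx:03d}",
            )
            peptides.append(annotate_peptide(pep))
        if idx >= n_phospho:
            break
    if idx < n_phospho:
        raise ConfigurationError(
            f"design space exhausted at {idx} peptides; requested {n_phospho}"
        )
    if control:
        chars = list(DEPHOS_TEMPLATE)
        chars[3] = chars[4] = chars[5] = "A"
        chars[6] = "S"
        chars[7] = "A"
        chars[9], chars[10] = "A", "E"
        ctrl = PhosphoPeptide(
            peptide_id="ctrl001",
            sequence="".join(chars),
            phospho_positions=frozenset(),
            code_id=f"code{n_phospho + 1:03d}",
        )
        peptides.append(annotate_peptide(ctrl))
    return peptides


# ---------------------------------------------------------------------------
# Library file I/O (TSV)
# ---------------------------------------------------------------------------

LIBRARY_COLUMNS = ["peptide_id", "code_id", "sequence", "acceptor", "plus1_residue"]


def library_to_frame(peptides) -> pd.DataFrame:
    rows = [
        {
            "peptide_id": p.peptide_id,
            "code_id": p.code_id,
            "sequence": p.canonical,
            "acceptor": p.acceptor,
            "plus1_residue": p.plus1_residue,
        }
        for p in peptides
    ]
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def write_library(peptides, path) -> None:
    library_to_frame(peptides).to_csv(path, sep="\t", index=False)


def read_library(path) -> list[PhosphoPeptide]:
    """Read a library TSV; phospho notation in `sequence` may be any accepted form."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("peptide_id", "code_id", "sequence") if c not in df.columns]
    if missing:
        raise ConfigurationError(f"library file missing columns: {missing}")
    codes = df["code_id"]
    if codes.duplicated().any():
        dups = sorted(codes[codes.duplicated()].unique())
        raise ConfigurationError(f"code_id not unique within library: {dups}")
    out = []
    for row in df.itertuples(index=False):
        plain, positions = parse_sequence(row.sequence)
        pep = PhosphoPeptide(
            peptide_id=row.peptide_id,
            sequence=plain,
            phospho_positions=positions,
            code_id=row.code_id,
        )
        out.append(annotate_peptide(pep) if len(positions) <= 1 else pep)
    return out
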