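"""Rule-based in silico enzymatic hydrolysis of protein sequences.

Emulates the "Enzyme action" style of the BIOPEP-UWM database: a protease is a
declarative :class:`CleavageRule` describing the residue context around a
scissile bond (P2 / P1 / P1'), and a digest is the set of fragments between
the bonds cut by at least one rule (simultaneous multi-enzyme action).

Conventions
-----------
* Sequences use the 20-letter standard amino-acid alphabet; ambiguous codes
  (B, J, O, U, X, Z) are rejected.
* Coordinates are 1-based inclusive.  "Bond index i" denotes the peptide bond
  between residue i and residue i+1, so valid bond indices are 1 .. L-1.
* For bond i: P1 = residue i, P1' = residue i+1, P2 = residue i-1.  A rule
  with a non-empty P2 class can never fire at bond 1 (there is no P2).
* Enzyme definitions are data (``data/enzymes.yaml``), never hard-coded; the
  packaged defaults follow the common Keil/BIOPEP conventions (trypsin: cut
  after K/R unless P follows; papain: hydrophobic P2 requirement; pepsin at
  pH 2: cut after F/L/W/Y unless P follows).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

_DATA_DIR = Path(__file__).parent / "data"
DEFAULT_RULE_FILE = _DATA_DIR / "enzymes.yaml"


class SequenceError(ValueError):
    """A sequence contains a residue outside the standard alphabet."""


def validate_sequence(sequence: str, *, what: str = "sequence") -> None:
    if not sequence:
        raise SequenceError(f"{what} is empty")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in STANDARD_AA:
            raise SequenceError(
                f"invalid residue {aa!r} at position {pos} of {what}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, what=f"protein {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageRule:
    """Declarative protease specificity around one scissile bond.

    Parameters
    ----------
    enzyme_name :
        Label for reports; carries no semantics.
    p1_classes :
        Residues allowed immediately N-terminal to the bond.  Empty means
        unrestricted P1 (the rule then needs a P2 constraint).
    p1prime_exclusions :
        Residues that *block* cleavage when immediately C-terminal.
    p2_classes :
        Residues required two positions N-terminal; empty = no constraint.
    """

    enzyme_name: str
    p1_classes: frozenset[str] = frozenset()
    p1prime_exclusions: frozenset[str] = frozenset()
    p2_classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("p1_classes", "p1prime_exclusions", "p2_classes"):
            residues = frozenset(getattr(self, name))
            object.__setattr__(self, name, residues)
            bad = residues - STANDARD_AA
            if bad:
                raise ValueError(
                    f"rule {self.enzyme_name!r}: {name} contains non-standard "
                    f"residues {sorted(bad)}"
                )
        if not self.p1_classes and not self.p2_classes:
            raise ValueError(
                f"rule {self.enzyme_name!r}: at least one of p1_classes / "
                "p2_classes must be non-empty"
            )

    def cuts(self, sequence: str, bond: int) -> bool:
        """Whether this rule cuts the bond between residues ``bond`` and ``bond+1``."""
        if not 1 <= bond < len(sequence):
            return False
        p1 = sequence[bond - 1]
        p1prime = sequence[bond]
        if self.p1_classes and p1 not in self.p1_classes:
            return False
        if p1prime in self.p1prime_exclusions:
            return False
        if self.p2_classes:
            if bond < 2:
                return False
            if sequence[bond - 2] not in self.p2_classes:
                return False
        return True


@dataclass(frozen=True)
class Peptide:
    """A released fragment with coordinates in its parent protein (1-based inclusive)."""

    sequence: str
    parent_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, what=f"peptide {self.sequence!r}")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide {self.sequence!r}: coordinates [{self.start}, {self.end}] "
                f"inconsistent with length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Rule file I/O
# ---------------------------------------------------------------------------

def load_rules(path: str | Path = DEFAULT_RULE_FILE,
               enzymes: Sequence[str] | None = None) -> list[CleavageRule]:
    """Load cleavage rules from a YAML rule file.

    ``enzymes`` selects (and orders) a subset by name; by default every rule
    in the file is returned in file order.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"rule file {path}: expected a mapping of enzyme -> rule")
    rules = {
        name: CleavageRule(
            enzyme_name=name,
            p1_classes=frozenset(spec.get("p1_classes") or ()),
            p1prime_exclusions=frozenset(spec.get("p1prime_exclusions") or ()),
            p2_classes=frozenset(spec.get("p2_classes") or ()),
        )
        for name, spec in raw.items()
    }
    if enzymes is None:
        return list(rules.values())
    missing = [e for e in enzymes if e not in rules]
    if missing:
        raise KeyError(
            f"enzymes {missing} not in rule file {path}; available: {sorted(rules)}"
        )
    return [rules[e] for e in enzymes]


def dump_rules(rules: Iterable[CleavageRule], path: str | Path) -> None:
    """Serialize rules back to YAML (sorted residue lists; round-trips exactly)."""
    payload = {
        r.enzyme_name: {
            "p1_classes": sorted(r.p1_classes),
            "p1prime_exclusions": sorted(r.p1prime_exclusions),
            "p2_classes": sorted(r.p2_classes),
        }
        for r in rules
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def cleavage_sites(protein: ProteinRecord,
                   rules: Sequence[CleavageRule]) -> set[int]:
    """Bond indices cut by at least one rule (simultaneous multi-enzyme union)."""
    if not rules:
        raise ValueError("at least one cleavage rule is required")
    seq = protein.sequence
    return {
        bond
        for bond in range(1, len(seq))
        if any(rule.cuts(seq, bond) for rule in rules)
    }


def digest(protein: ProteinRecord, rules: Sequence[CleavageRule],
           *, sequential: bool = False) -> list[Peptide]:
    """Hydrolyze a protein into the maximal fragments between cut bonds.

    With ``sequential=True`` the rules are applied one enzyme at a time, each
    acting on the fragments left by the previous one, instead of the default
    simultaneous union of cut sites.  For context-free rules the results
    coincide except where one enzyme's cut removes the P2 context another
    rule needs.
    """
    if sequential:
        fragments = [Peptide(protein.sequence, protein.id, 1, len(protein))]
        for rule in rules:
            fragments = [
                piece
                for frag in fragments
                for piece in _digest_fragment(frag, [rule])
            ]
        return fragments
    sites = cleavage_sites(protein, rules)
    return _fragments_between(protein.id, protein.sequence, sites, offset=0)


def _fragments_between(parent_id: str, seq: str, sites: set[int],
                       offset: int) -> list[Peptide]:
    bounds = [0, *sorted(sites), len(seq)]
    return [
        Peptide(seq[a:b], parent_id, offset + a + 1, offset + b)
        for a, b in itertools.pairwise(bounds)
    ]


def _digest_fragment(frag: Peptide, rules: Sequence[CleavageRule]) -> list[Peptide]:
    """Digest a fragment, keeping coordinates in the original parent frame."""
    record = ProteinRecord(frag.parent_id, frag.sequence)
    sites = cleavage_sites(record, rules)
    return _fragments_between(frag.parent_id, frag.sequence, sites,
                              offset=frag.start - 1)


def gi_digest(peptide: Peptide,
              stages: Sequence[Sequence[CleavageRule]]
              ) -> tuple[list[Peptide], bool]:
    """Sequential multi-stage digestion (gastrointestinal simulation).

    Each stage (e.g. pepsin at pH 2, then trypsin) digests every fragment
    surviving the previous stage.  Returns the final fragments and a flag
    telling whether the input peptide emerged intact.
    """
    fragments = [peptide]
    for stage in stages:
        if not stage:
            continue
        fragments = [
            piece
            for frag in fragments
            for piece in _digest_fragment(frag, stage)
        ]
    survived = any(
        f.sequence == peptide.sequence and f.start == peptide.start
        for f in fragments
    )
    return fragments, survived


def default_gi_stages(path: str | Path = DEFAULT_RULE_FILE
                      ) -> list[list[CleavageRule]]:
    """Pepsin (pH 2) stage followed by a trypsin stage, from the rule file."""
    pepsin, trypsin = load_rules(path, ["pepsin_ph2", "trypsin"])
    return [[pepsin], [trypsin]]


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read one or more protein records from a FASTA file."""
    records = [
        ProteinRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_peptides_tsv(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Write released peptides as TSV: parent_id, start, end, length, sequence."""
    with open(path, "w") as fh:
        fh.write("parent_id\tstart\tend\tlength\tsequence\n")
        for p in peptides:
            fh.write(f"{p.parent_id}\t{p.start}\t{p.end}\t{len(p)}\t{p.sequence}\n")
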