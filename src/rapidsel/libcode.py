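"""Library architecture and read decoding under a reprogrammed genetic code.

The display library encodes peptides as::

    5'-[upstream anchor][initiator codon][random region: N x NNK][Cys codon][spacer][stop]-3'

The initiator codon is reassigned to a non-standard initiator residue
(rendered ``'Y'`` for the l-library and lowercase ``'y'`` for the
d-library); every other codon follows the standard genetic code.
Decoding locates the constant regions, translates the variable window and
either accepts the read or rejects it with a single explicit reason.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from Bio.Data import CodonTable

__all__ = [
    "STOP",
    "DNA_BASES",
    "RejectReason",
    "GeneticCode",
    "LibraryArchitecture",
    "DecodedPeptide",
    "AmbiguousBaseError",
    "translate_codon",
    "check_nnk",
    "decode_read",
    "decode_reads",
    "nnk_codons",
    "nnk_codons_for",
    "nnk_residue_distribution",
    "reverse_complement",
    "tally_rejections",
]

STOP = "*"
DNA_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard codon -> residue map, stops rendered as '*'.
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STANDARD_CODE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
_STANDARD_CODE.update({codon: STOP for codon in _STANDARD_TABLE.stop_codons})
assert len(_STANDARD_CODE) == 64


class AmbiguousBaseError(ValueError):
    """Raised when a codon contains a base outside {A, C, G, T}."""


class RejectReason(str, enum.Enum):
    NONE = "none"
    ANCHOR_NOT_FOUND = "anchor_not_found"
    INTERNAL_STOP = "internal_stop"
    AMBIGUOUS_BASE = "ambiguous_base"
    LENGTH_MISMATCH = "length_mismatch"
    NNK_VIOLATION_DISCARDED = "nnk_violation_discarded"


@dataclass(frozen=True)
class GeneticCode:
    """A total codon table plus the initiator reassignment.

    ``codon_to_residue`` maps all 64 codons to one-letter residues (stops
    as ``'*'``); ``initiator_override`` maps the initiator codon to the
    reprogrammed initiator symbol and applies at the initiator position
    only.
    """

    codon_to_residue: Mapping[str, str] = field(
        default_factory=lambda: dict(_STANDARD_CODE)
    )
    initiator_override: Mapping[str, str] = field(
        default_factory=lambda: {"ATG": "Y"}
    )

    def __post_init__(self) -> None:
        if set(self.codon_to_residue) != set(_STANDARD_CODE):
            raise ValueError("codon_to_residue must map exactly the 64 codons")

    @classmethod
    def for_library(cls, initiator_symbol: str, initiator_codon: str = "ATG") -> "GeneticCode":
        return cls(initiator_override={initiator_codon: initiator_symbol})


@dataclass(frozen=True)
class LibraryArchitecture:
    """Constant read layout of one display library."""

    upstream_anchor: str
    initiator_codon: str = "ATG"
    random_codon_count: int = 15
    anchor_codon: str = "TGC"
    spacer_nucleotides: str = "GGTAGCGGTAGCGGTAGC"  # G-S-G-S-G-S
    stop_codons: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})
    initiator_symbol: str = "Y"
    max_flank_mismatches: int = 0

    def __post_init__(self) -> None:
        for name in ("initiator_codon", "anchor_codon"):
            codon = getattr(self, name)
            if len(codon) != 3 or not set(codon) <= DNA_BASES:
                raise ValueError(f"{name} must be a length-3 codon over ACGT: {codon!r}")
        for codon in self.stop_codons:
            if len(codon) != 3 or not set(codon) <= DNA_BASES:
                raise ValueError(f"invalid stop codon {codon!r}")
        if not set(self.upstream_anchor) <= DNA_BASES:
            raise ValueError("upstream_anchor must be over ACGT")
        if self.random_codon_count < 1:
            raise ValueError("random_codon_count must be >= 1")
        if len(self.initiator_symbol) != 1:
            raise ValueError("initiator_symbol must be a single character")
        if self.max_flank_mismatches < 0:
            raise ValueError("max_flank_mismatches must be >= 0")

    @property
    def library_tag(self) -> str:
        """'L' for an uppercase initiator symbol, 'D' for lowercase."""
        return "L" if self.initiator_symbol.isupper() else "D"

    @property
    def peptide_length(self) -> int:
        return self.random_codon_count + 2

    @property
    def genetic_code(self) -> GeneticCode:
        return GeneticCode.for_library(self.initiator_symbol, self.initiator_codon)

    def coding_region(self, random_codons: str) -> str:
        """Assemble a full-length error-free amplicon around a random region."""
        if len(random_codons) != 3 * self.random_codon_count:
            raise ValueError("random region has wrong length")
        return (
            self.upstream_anchor
            + self.initiator_codon
            + random_codons
            + self.anchor_codon
            + self.spacer_nucleotides
            + "TAG"
        )


@dataclass(frozen=True)
class DecodedPeptide:
    """The result of decoding one read."""

    peptide: str
    dna_random_region: str
    library_tag: str
    accepted: bool
    reject_reason: RejectReason = RejectReason.NONE
    nnk_violations: int = 0

    def __post_init__(self) -> None:
        if self.accepted and self.reject_reason is not RejectReason.NONE:
            raise ValueError("accepted records must carry reject_reason none")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str, code: GeneticCode, is_initiator: bool = False) -> str:
    """Translate a codon; the initiator position may be reassigned.

    Returns a one-letter residue or :data:`STOP`.  Raises
    :class:`AmbiguousBaseError` for any base outside {A, C, G, T}.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    if not set(codon) <= DNA_BASES:
        raise AmbiguousBaseError(f"ambiguous base in codon {codon!r}")
    if is_initiator and codon in code.initiator_override:
        return code.initiator_override[codon]
    return code.codon_to_residue[codon]


def check_nnk(codon: str) -> bool:
    """True iff the codon satisfies the NNK constraint (wobble base G or T)."""
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    return codon[2] in "GT"


def nnk_codons() -> list[str]:
    """The 32 NNK codons, lexicographically ordered."""
    return [
        "".join(c)
        for c in itertools.product("ACGT", "ACGT", "GT")
    ]


def nnk_codons_for(residue: str) -> list[str]:
    """NNK codons encoding ``residue`` (uppercased; initiator symbols map to Tyr)."""
    target = residue.upper()
    return [c for c in nnk_codons() if _STANDARD_CODE[c] == target]


def nnk_residue_distribution() -> dict[str, float]:
    """Exact residue frequencies implied by uniform NNK codon usage
    conditioned on non-stop (31 coding codons of 32)."""
    coding = [c for c in nnk_codons() if _STANDARD_CODE[c] != STOP]
    dist: dict[str, float] = {}
    for codon in coding:
        aa = _STANDARD_CODE[codon]
        dist[aa] = dist.get(aa, 0.0) + 1.0 / len(coding)
    return dist


def _find_with_mismatches(read: str, pattern: str, max_mismatches: int) -> int:
    """Leftmost index where ``pattern`` matches ``read`` with at most
    ``max_mismatches`` substitutions; -1 if none."""
    if max_mismatches == 0:
        return read.find(pattern)
    n, m = len(read), len(pattern)
    for start in range(n - m + 1):
        mism = 0
        window = read[start : start + m]
        for a, b in zip(window, pattern):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            return start
    return -1


def decode_read(
    read: str,
    arch: LibraryArchitecture,
    *,
    reject_internal_stop: bool = True,
    strict_nnk: bool = False,
    anchor_scan_codons: int = 0,
) -> DecodedPeptide:
    """Decode one read into a peptide under the library architecture.

    The upstream anchor is located on the forward strand first and, failing
    that, on the reverse complement.  The initiator codon and the downstream
    Cys codon must sit at their architectural positions.  Rejections carry
    the first applicable reason in the order anchor_not_found ->
    ambiguous_base -> internal_stop -> length_mismatch; NNK violations in
    the random region are tallied and, in strict mode only, rejected.

    ``anchor_scan_codons`` > 0 enables a tolerant mode that scans for the
    Cys codon within that many codons of its expected position; off-position
    hits are rejected as length_mismatch (indel in the random region).
    """
    read = read.upper()
    tag = arch.library_tag
    code = arch.genetic_code

    def rejected(reason: RejectReason, region: str = "") -> DecodedPeptide:
        return DecodedPeptide(
            peptide="",
            dna_random_region=region,
            library_tag=tag,
            accepted=False,
            reject_reason=reason,
        )

    pos = _find_with_mismatches(read, arch.upstream_anchor, arch.max_flank_mismatches)
    if pos < 0:
        rc = reverse_complement(read)
        pos = _find_with_mismatches(rc, arch.upstream_anchor, arch.max_flank_mismatches)
        if pos < 0:
            return rejected(RejectReason.ANCHOR_NOT_FOUND)
        read = rc

    start = pos + len(arch.upstream_anchor)
    region_len = 3 * arch.random_codon_count
    anchor_at = start + 3 + region_len
    if anchor_at + 3 > len(read):
        # read too short for the architecture footprint
        return rejected(RejectReason.ANCHOR_NOT_FOUND)

    window = read[start : anchor_at + 3]
    initiator = window[:3]
    region = window[3 : 3 + region_len]
    cys_codon = window[3 + region_len :]

    if cys_codon != arch.anchor_codon or initiator != arch.initiator_codon:
        if anchor_scan_codons > 0 and initiator == arch.initiator_codon:
            for shift in range(1, anchor_scan_codons + 1):
                for cand in (anchor_at - 3 * shift, anchor_at + 3 * shift):
                    if 0 <= cand and cand + 3 <= len(read) and read[cand : cand + 3] == arch.anchor_codon:
                        return rejected(RejectReason.LENGTH_MISMATCH)
        return rejected(RejectReason.ANCHOR_NOT_FOUND)

    if not set(window) <= DNA_BASES:
        return rejected(RejectReason.AMBIGUOUS_BASE, region)

    residues = [translate_codon(initiator, code, is_initiator=True)]
    violations = 0
    for i in range(arch.random_codon_count):
        codon = region[3 * i : 3 * i + 3]
        aa = translate_codon(codon, code)
        if aa == STOP:
            if reject_internal_stop:
                return rejected(RejectReason.INTERNAL_STOP, region)
            aa = STOP
        if not check_nnk(codon):
            violations += 1
        residues.append(aa)
    residues.append(translate_codon(cys_codon, code))

    if strict_nnk and violations > 0:
        return rejected(RejectReason.NNK_VIOLATION_DISCARDED, region)

    return DecodedPeptide(
        peptide="".join(residues),
        dna_random_region=region,
        library_tag=tag,
        accepted=True,
        nnk_violations=violations,
    )


def decode_reads(
    reads: Iterable[str], arch: LibraryArchitecture, **kwargs
) -> Iterator[DecodedPeptide]:
    for read in reads:
        yield decode_read(read, arch, **kwargs)


def tally_rejections(decoded: Iterable[DecodedPeptide]) -> dict[str, int]:
    """Count records by rejection reason ('accepted' for accepted reads)."""
    tally: dict[str, int] = {}
    for rec in decoded:
        key = "accepted" if rec.accepted else rec.reject_reason.value
        tally[key] = tally.get(key, 0) + 1
    return tally
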