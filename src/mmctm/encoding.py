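"""Encode raw SNV and SV calls into mutation-category count matrices.

SNVs are encoded pyrimidine-centrically: a substitution with a purine
reference base is reverse-complemented together with its flanking bases, so
every call maps to one of 6 substitution types (C>A, C>G, C>T, T>A, T>C,
T>G).  With the two +/-1 flanking reference bases this yields the standard
96-category trinucleotide-context space, or a 14-value independent-feature
decomposition (6 substitution types + 4 values per flank).

SVs are encoded by rearrangement type (deletion, tandem duplication,
inversion, foldback inversion, translocation), breakpoint-homology length
bin (0-1, 2-5, >5 bp) and breakpoint distance bin (<10kbp, 10-100kbp,
100kbp-1Mbp, 1-10Mbp, >10Mbp); translocations carry no distance bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .containers import CategorySpace, CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SnvCall",
    "SvCall",
    "EncodingError",
    "SkippedCall",
    "EncodingReport",
    "snv_category_space",
    "snv_independent_space",
    "sv_category_space",
    "encode_snv_context",
    "encode_independent",
    "encode_sv",
    "build_count_matrix",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = ("A", "C", "G", "T")
_PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SV_TYPES = ("DEL", "DUP", "FBI", "INV", "TR")
_SV_TYPE_ALIASES = {
    "deletion": "DEL", "del": "DEL",
    "tandem_duplication": "DUP", "duplication": "DUP", "dup": "DUP",
    "inversion": "INV", "inv": "INV",
    "foldback_inversion": "FBI", "foldback": "FBI", "fbi": "FBI",
    "translocation": "TR", "tr": "TR",
}
HOMOLOGY_BINS = ("0-1", "2-5", ">5")
DISTANCE_BINS = ("<10kbp", "10-100kbp", "100kbp-1Mbp", "1-10Mbp", ">10Mbp")
# half-open distance partition, bp
_DISTANCE_EDGES = (10_000, 100_000, 1_000_000, 10_000_000)


class EncodingError(ValueError):
    """A call that violates encoder preconditions (hard rejection)."""


class SkippedCall(Exception):
    """A call outside the encodable space (indel, N-context, ...); logged."""


@dataclass(frozen=True)
class SnvCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str


@dataclass(frozen=True)
class SvCall:
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    homology_bp: int
    sample_id: str


@dataclass
class EncodingReport:
    """Per-sample tallies of encoded and skipped calls."""

    encoded: dict[str, int] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)
    skip_reasons: list[str] = field(default_factory=list)

    def count(self, sample_id: str, ok: bool, reason: str | None = None) -> None:
        book = self.encoded if ok else self.skipped
        book[sample_id] = book.get(sample_id, 0) + 1
        if reason is not None:
            self.skip_reasons.append(reason)

    @property
    def n_encoded(self) -> int:
        return sum(self.encoded.values())

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


def snv_category_space() -> CategorySpace:
    """The 96 trinucleotide-context categories, ordered by substitution
    type, then 5' flank, then 3' flank."""
    labels = tuple(
        f"{five}[{sub}]{three}"
        for sub, five, three in product(_PYRIMIDINE_SUBS, _BASES, _BASES)
    )
    return CategorySpace("SNV", labels, encoding="full")


def snv_independent_space() -> CategorySpace:
    """The 14 independent SNV feature values (6 + 4 + 4)."""
    labels = (
        _PYRIMIDINE_SUBS
        + tuple(f"5':{b}" for b in _BASES)
        + tuple(f"3':{b}" for b in _BASES)
    )
    return CategorySpace("SNV", labels, encoding="independent",
                         feature_arity=(6, 4, 4))


def sv_category_space(include_foldback: bool = True) -> CategorySpace:
    """SV categories: type x homology x distance, translocations without a
    distance bin.  63 labels with foldback inversions, 48 without."""
    types = [t for t in SV_TYPES if include_foldback or t != "FBI"]
    labels = []
    for t in types:
        for hom in HOMOLOGY_BINS:
            if t == "TR":
                labels.append(f"TR:{hom}")
            else:
                labels.extend(f"{t}:{hom}:{d}" for d in DISTANCE_BINS)
    return CategorySpace("SV", tuple(labels), encoding="full")


def _fetch_base(reference, chrom: str, pos: int) -> str:
    """1-based single-base fetch from a pyfaidx Fasta or a dict of strings."""
    try:
        seq = reference[chrom]
    except KeyError as exc:
        raise EncodingError(f"chromosome {chrom!r} absent from reference") from exc
    if pos < 1 or pos > len(seq):
        raise EncodingError(f"position {chrom}:{pos} outside reference")
    return str(seq[pos - 1:pos]).upper()


def _normalize_snv(call: SnvCall, reference) -> tuple[str, str, str]:
    """Return (substitution, 5' flank, 3' flank) on the pyrimidine strand."""
    ref, alt = call.ref.upper(), call.alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        raise SkippedCall(f"{call.sample_id} {call.chrom}:{call.pos}: not a single-base substitution")
    if ref == alt:
        raise SkippedCall(f"{call.sample_id} {call.chrom}:{call.pos}: ref equals alt")
    if ref not in _BASES or alt not in _BASES:
        raise SkippedCall(f"{call.sample_id} {call.chrom}:{call.pos}: non-ACGT allele")
    genome_ref = _fetch_base(reference, call.chrom, call.pos)
    if genome_ref != ref:
        raise EncodingError(
            f"{call.sample_id} {call.chrom}:{call.pos}: reference mismatch "
            f"(call {ref}, genome {genome_ref})"
        )
    five = _fetch_base(reference, call.chrom, call.pos - 1)
    three = _fetch_base(reference, call.chrom, call.pos + 1)
    if five not in _BASES or three not in _BASES:
        raise SkippedCall(f"{call.sample_id} {call.chrom}:{call.pos}: ambiguous flanking base")
    if ref in ("A", "G"):  # purine reference: flip to the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    return f"{ref}>{alt}", five, three


def encode_snv_context(call: SnvCall, reference) -> str:
    """Encode an SNV into its trinucleotide-context category, e.g. ``A[C>T]G``."""
    sub, five, three = _normalize_snv(call, reference)
    return f"{five}[{sub}]{three}"


def encode_independent(call: SnvCall, reference) -> tuple[str, str, str]:
    """Encode an SNV as its (substitution, 5' flank, 3' flank) feature tuple."""
    sub, five, three = _normalize_snv(call, reference)
    return sub, f"5':{five}", f"3':{three}"


def context_to_features(label: str) -> tuple[str, str, str]:
    """Invert a 96-context label into its independent feature tuple."""
    five, rest = label.split("[")
    sub, three = rest.split("]")
    return sub, f"5':{five}", f"3':{three}"


def homology_bin(homology_bp: int) -> str:
    if homology_bp < 0:
        raise EncodingError(f"negative homology length {homology_bp}")
    if homology_bp <= 1:
        return "0-1"
    if homology_bp <= 5:
        return "2-5"
    return ">5"


def distance_bin(distance_bp: int) -> str:
    for edge, label in zip(_DISTANCE_EDGES, DISTANCE_BINS):
        if distance_bp < edge:
            return label
    return DISTANCE_BINS[-1]


def encode_sv(call: SvCall) -> str:
    """Encode an SV call into its ``TYPE:HOM`` or ``TYPE:HOM:DIST`` category."""
    key = call.sv_type.strip().lower()
    sv_type = _SV_TYPE_ALIASES.get(key, call.sv_type.upper())
    if sv_type not in SV_TYPES:
        raise EncodingError(f"unknown SV type {call.sv_type!r}")
    hom = homology_bin(call.homology_bp)
    if sv_type == "TR":
        return f"TR:{hom}"
    if call.chrom1 != call.chrom2:
        raise EncodingError(
            f"{call.sample_id}: {sv_type} with breakpoints on different "
            f"chromosomes ({call.chrom1}, {call.chrom2})"
        )
    return f"{sv_type}:{hom}:{distance_bin(abs(call.pos2 - call.pos1))}"


def _encode_one(call, space: CategorySpace, reference) -> list[str]:
    if isinstance(call, SnvCall):
        if reference is None:
            raise ValueError("SNV encoding requires a reference genome")
        if space.encoding == "independent":
            return list(encode_independent(call, reference))
        return [encode_snv_context(call, reference)]
    if isinstance(call, SvCall):
        return [encode_sv(call)]
    raise TypeError(f"cannot encode {type(call).__name__}")


def build_count_matrix(calls, category_space: CategorySpace, reference=None,
                       sample_ids: list[str] | None = None,
                       ) -> tuple[CountMatrix, EncodingReport]:
    """Tally encoded calls into a sample x category count matrix.

    Calls that fall outside the encodable space (indels, ambiguous contexts)
    are skipped and tallied in the returned :class:`EncodingReport`; calls
    that violate preconditions (reference mismatch, malformed SVs) raise
    :class:`EncodingError`.  For independent encodings each call increments
    one cell per feature.
    """
    if sample_ids is None:
        seen: dict[str, None] = {}
        for c in calls:
            seen.setdefault(c.sample_id, None)
        sample_ids = list(seen)
    if not calls:
        logger.warning("no calls supplied; returning an empty count matrix")
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    label_index = {lab: j for j, lab in enumerate(category_space.labels)}
    counts = np.zeros((len(sample_ids), len(category_space)), dtype=np.int64)
    report = EncodingReport()
    for call in calls:
        if call.sample_id not in sample_index:
            raise EncodingError(f"unknown sample_id {call.sample_id!r}")
        try:
            labels = _encode_one(call, category_space, reference)
        except SkippedCall as why:
            report.count(call.sample_id, ok=False, reason=str(why))
            logger.warning("skipped call: %s", why)
            continue
        for lab in labels:
            counts[sample_index[call.sample_id], label_index[lab]] += 1
        report.count(call.sample_id, ok=True)
    cm = CountMatrix(list(sample_ids), category_space, counts)
    for s in cm.zero_samples():
        logger.warning("sample %s has zero encoded calls", s)
    return cm, report
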