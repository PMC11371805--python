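"""Coding-consequence annotation and splice-disruption isoform prediction.

Covers the annotation stage of the mapping pipeline: classifying variants
inside the candidate interval against a gene model (synonymous / missense /
nonsense / splice-site / frameshift ...), enumerating the aberrant
transcripts a disrupted splice donor can generate, translating them, and
reporting which protein domains a truncation removes.

The splice model is deliberately minimal and generative: the donor site is
the first two intronic nucleotides after an exon (canonically GT) and the
acceptor the last two; when a donor is disrupted, the spliceosome either
skips the upstream exon or reads into the intron until the next cryptic GT
dinucleotide, retaining the intron prefix before it.  No splice-strength
scoring is attempted.  Translation uses the standard genetic code from the
reference start codon of the transcript.

Category precedence for variants with several effects:
``splice_donor``/``splice_acceptor`` > ``nonsense`` > ``frameshift_indel`` >
``missense`` > ``inframe_indel`` > ``synonymous``; secondary effects are
kept in the ``detail`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .coseg_classifier import VariantSite
from .errors import ValidationError

__all__ = [
    "GeneModel",
    "Domain",
    "DomainTable",
    "AberrantIsoform",
    "ConsequenceCall",
    "TranslationResult",
    "classify_coding_variant",
    "enumerate_aberrant_isoforms",
    "translate_isoform",
    "report_truncation",
    "load_domain_table",
]


def get_seq(genome, scaffold: str, start: int, end: int) -> str:
    """Fetch genome[start:end) (0-based) from a pyfaidx Fasta or a plain dict."""
    record = genome[scaffold]
    if isinstance(record, str):
        return record[start:end].upper()
    return str(record[start:end]).upper()


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GeneModel:
    """One transcript: exon/CDS structure on a scaffold (0-based half-open).

    ``exons`` and ``cds`` are sorted by genomic start regardless of strand;
    transcript order is derived from ``strand``.  The reference spliced CDS
    must be a whole number of codons.
    """

    gene_id: str
    transcript_id: str
    scaffold: str
    strand: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r} for {self.transcript_id}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValidationError(f"overlapping exons in {self.transcript_id}")
        for c_s, c_e in self.cds:
            if not any(s <= c_s and c_e <= e for s, e in self.exons):
                raise ValidationError(
                    f"CDS segment {c_s}-{c_e} outside exons in {self.transcript_id}"
                )
        if self.cds and sum(e - s for s, e in self.cds) % 3 != 0:
            raise ValidationError(
                f"spliced CDS of {self.transcript_id} is not a whole number of codons"
            )

    # --- structure -------------------------------------------------------
    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_transcript_order(self) -> List[Tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns_transcript_order(self) -> List[Tuple[int, int]]:
        """Genomic intron blocks, ordered 5'->3' along the transcript."""
        introns = [
            (e1[1], e2[0]) for e1, e2 in zip(self.exons, self.exons[1:])
        ]
        return introns if self.strand == "+" else list(reversed(introns))

    def donor_region(self, intron_index: int) -> Tuple[int, int]:
        """Genomic coordinates of the 2-nt donor of the i-th intron (transcript order)."""
        s, e = self.introns_transcript_order()[intron_index]
        return (s, s + 2) if self.strand == "+" else (e - 2, e)

    def acceptor_region(self, intron_index: int) -> Tuple[int, int]:
        s, e = self.introns_transcript_order()[intron_index]
        return (e - 2, e) if self.strand == "+" else (s, s + 2)

    def intron_seq(self, intron_index: int, genome) -> str:
        """Intron sequence in transcript orientation."""
        s, e = self.introns_transcript_order()[intron_index]
        seq = get_seq(genome, self.scaffold, s, e)
        return seq if self.strand == "+" else revcomp(seq)

    # --- sequences -------------------------------------------------------
    def transcript_seq(self, genome) -> str:
        parts = [
            get_seq(genome, self.scaffold, s, e) for s, e in self.exons
        ]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_seq(self, genome) -> str:
        parts = [get_seq(genome, self.scaffold, s, e) for s, e in self.cds]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)

    def reference_protein(self, genome) -> str:
        protein = str(Seq(self.cds_seq(genome)).translate())
        return protein.split("*")[0]

    def genomic_to_transcript(self, gpos: int) -> Optional[int]:
        """Transcript offset of a genomic position, or None if intronic."""
        off = 0
        for s, e in self.exons_transcript_order():
            if s <= gpos < e:
                return off + (gpos - s if self.strand == "+" else e - 1 - gpos)
            off += e - s
        return None

    def cds_start_genomic(self) -> int:
        """Genomic coordinate of the first CDS base in transcript order."""
        if not self.cds:
            raise ValidationError(f"{self.transcript_id} has no CDS")
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1] - 1

    def cds_start_offset(self) -> int:
        off = self.genomic_to_transcript(self.cds_start_genomic())
        assert off is not None
        return off


@dataclass(frozen=True)
class Domain:
    name: str
    aa_start: int  # 1-based inclusive
    aa_end: int


class DomainTable:
    """Protein-domain coordinate table (1-based inclusive on the reference protein)."""

    def __init__(self, domains: Sequence[Domain], protein_length: Optional[int] = None):
        for d in domains:
            if not (1 <= d.aa_start <= d.aa_end):
                raise ValidationError(f"bad domain coordinates for {d.name}")
            if protein_length is not None and d.aa_end > protein_length:
                raise ValidationError(
                    f"domain {d.name} extends past the protein ({d.aa_end} > {protein_length})"
                )
        self.domains = list(domains)

    def __iter__(self):
        return iter(self.domains)

    def __len__(self):
        return len(self.domains)


def load_domain_table(path: Optional[str | Path] = None) -> DomainTable:
    """Load a domain TSV (name, aa_start, aa_end).

    Without a path, loads the bundled premelanosome-protein (PMEL) domain
    map used in the worked examples: signal peptide, core amyloid fragment,
    PKD domain, repeat domain, convertase cleavage site, Kringle-like
    domain, transmembrane helix and cytoplasmic domain over a 713-aa
    protein.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "pmel_domains.tsv"
    domains = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["name", "aa_start", "aa_end"]:
            raise ValidationError("domain table must have columns name, aa_start, aa_end")
        for line in fh:
            if not line.strip():
                continue
            name, s, e = line.rstrip("\n").split("\t")[:3]
            domains.append(Domain(name, int(s), int(e)))
    return DomainTable(domains)


@dataclass
class ConsequenceCall:
    """Single-category consequence of one variant on one transcript."""

    variant: VariantSite
    gene_id: str
    transcript_id: str
    category: str
    aa_change: Optional[str] = None
    detail: Tuple[str, ...] = ()
    domains_lost: Tuple[str, ...] = ()


@dataclass
class AberrantIsoform:
    """A splice-disrupted derivative of a reference transcript.

    ``exon_skip``: the exon upstream of the disrupted donor is dropped.
    ``intron_retention``: the first ``retained_length`` bp of the disrupted
    intron stay in the transcript (the retained block ends immediately
    before a cryptic GT donor).
    """

    kind: str  # exon_skip | intron_retention
    disrupted_intron: int  # transcript-order intron index
    skipped_exon: Optional[int] = None  # transcript-order exon index
    retained_length: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("exon_skip", "intron_retention"):
            raise ValidationError(f"unknown isoform kind {self.kind!r}")
        if self.kind == "intron_retention" and self.retained_length <= 0:
            raise ValidationError("intron_retention requires retained_length > 0")


@dataclass
class TranslationResult:
    protein: str
    stop_offset: Optional[int]  # transcript offset of the stop codon, None = runoff
    runoff: bool = False
    start_lost: bool = False
    truncated: bool = False


# ---------------------------------------------------------------------------
# variant classification
# ---------------------------------------------------------------------------

def _substituted_region(seq: str, region_start: int, pos: int, ref: str, alt: str) -> str:
    """Apply a length-preserving substitution to a plus-strand region string."""
    off = pos - region_start
    if off + len(ref) <= 0 or off >= len(seq):
        return seq
    lo = max(0, off)
    hi = min(len(seq), off + len(ref))
    return seq[:lo] + alt[lo - off : hi - off] + seq[hi:]


def classify_coding_variant(
    model: GeneModel,
    variant: VariantSite,
    genome,
    flank: int = 5000,
) -> ConsequenceCall:
    """Classify one biallelic variant against one transcript model.

    The variant's REF allele is checked against the genome (mismatch raises
    :class:`ValidationError`).  A variant overlapping a 2-nt donor/acceptor
    window is a splice variant whenever the ALT allele actually changes the
    spliced dinucleotide; any exonic sub-effect is recorded in ``detail``.
    """
    pos, ref, alt = variant.pos, variant.ref, variant.alt
    span = (pos, pos + len(ref))
    g_start, g_end = model.span
    if span[1] <= g_start - flank or span[0] >= g_end + flank:
        return ConsequenceCall(variant, model.gene_id, model.transcript_id, "intergenic")

    observed = get_seq(genome, model.scaffold, span[0], span[1])
    if observed != ref.upper():
        raise ValidationError(
            f"reference mismatch at {model.scaffold}:{pos + 1}: "
            f"VCF REF {ref!r} vs genome {observed!r}"
        )

    detail: List[str] = []

    def overlaps(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
        return a[0] < b[1] and b[0] < a[1]

    # splice sites take precedence when the site dinucleotide really changes
    splice_category = None
    for i in range(len(model.exons) - 1):
        for region, cat in (
            (model.donor_region(i), "splice_donor"),
            (model.acceptor_region(i), "splice_acceptor"),
        ):
            if not overlaps(span, region):
                continue
            site_ref = get_seq(genome, model.scaffold, region[0], region[1])
            site_alt = _substituted_region(site_ref, region[0], pos, ref, alt)
            if len(ref) != len(alt) or site_alt != site_ref:
                splice_category = cat
                detail.append(f"{cat}_dinucleotide:{site_ref}>{site_alt}"
                              if len(ref) == len(alt) else f"{cat}_indel")

    exonic = any(overlaps(span, e) for e in model.exons)
    coding = any(overlaps(span, c) for c in model.cds)

    aa_change = None
    sub_category = None
    if coding and len(ref) == len(alt):
        ref_prot, alt_prot = _proteins_with_substitution(model, genome, pos, ref, alt)
        if alt_prot == ref_prot:
            sub_category = "synonymous"
        elif len(alt_prot) < len(ref_prot):
            sub_category = "nonsense"
            aa_change = f"{ref_prot[len(alt_prot)]}{len(alt_prot) + 1}*"
        else:
            sub_category = "missense"
            k = next(
                (i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b), None
            )
            if k is not None:
                aa_change = f"{ref_prot[k]}{k + 1}{alt_prot[k]}"
            if len(alt_prot) > len(ref_prot):
                detail.append("stop_lost")
    elif coding:
        shift = abs(len(ref) - len(alt)) % 3
        sub_category = "frameshift_indel" if shift else "inframe_indel"

    if splice_category is not None:
        if sub_category is not None:
            detail.append(f"exonic:{sub_category}" + (f":{aa_change}" if aa_change else ""))
        return ConsequenceCall(
            variant, model.gene_id, model.transcript_id, splice_category,
            aa_change=None, detail=tuple(detail),
        )
    if sub_category is not None:
        return ConsequenceCall(
            variant, model.gene_id, model.transcript_id, sub_category,
            aa_change=aa_change, detail=tuple(detail),
        )
    if exonic:
        return ConsequenceCall(variant, model.gene_id, model.transcript_id, "UTR")
    if g_start <= span[0] and span[1] <= g_end:
        return ConsequenceCall(variant, model.gene_id, model.transcript_id, "intronic")
    return ConsequenceCall(variant, model.gene_id, model.transcript_id, "intergenic")


def _proteins_with_substitution(
    model: GeneModel, genome, pos: int, ref: str, alt: str
) -> Tuple[str, str]:
    """Reference and substituted proteins for a length-preserving variant."""
    ref_parts = []
    alt_parts = []
    for s, e in model.cds:
        part = get_seq(genome, model.scaffold, s, e)
        ref_parts.append(part)
        alt_parts.append(_substituted_region(part, s, pos, ref, alt))
    ref_cds = "".join(ref_parts)
    alt_cds = "".join(alt_parts)
    if model.strand == "-":
        ref_cds, alt_cds = revcomp(ref_cds), revcomp(alt_cds)
    ref_prot = str(Seq(ref_cds).translate()).split("*")[0]
    alt_prot = str(Seq(alt_cds).translate()).split("*")[0]
    return ref_prot, alt_prot


# ---------------------------------------------------------------------------
# aberrant isoform enumeration and translation
# ---------------------------------------------------------------------------

def enumerate_aberrant_isoforms(
    model: GeneModel,
    disrupted_intron: int,
    genome,
    max_scan: int = 2000,
) -> List[AberrantIsoform]:
    """Enumerate transcripts a disrupted donor can generate.

    Emits (a) the exon-skip isoform dropping the exon immediately upstream
    of the disrupted donor and (b) one intron-retention isoform per cryptic
    GT dinucleotide within the first ``max_scan`` bp of the intron
    (transcript orientation), retaining the intron prefix up to, and
    excluding, that GT.  Offset 0 — the disrupted donor itself — is never a
    cryptic site.  Reference splicing is not emitted.
    """
    introns = model.introns_transcript_order()
    if not (0 <= disrupted_intron < len(introns)):
        raise ValidationError(
            f"intron index {disrupted_intron} out of range for {model.transcript_id}"
        )
    intron = model.intron_seq(disrupted_intron, genome)
    if len(intron) < 2:
        raise ValidationError("disrupted intron shorter than 2 bp")
    isoforms = [
        AberrantIsoform(
            kind="exon_skip",
            disrupted_intron=disrupted_intron,
            skipped_exon=disrupted_intron,
        )
    ]
    limit = min(max_scan, len(intron) - 1)
    for off in range(1, limit):
        if intron[off : off + 2] == "GT":
            isoforms.append(
                AberrantIsoform(
                    kind="intron_retention",
                    disrupted_intron=disrupted_intron,
                    retained_length=off,
                )
            )
    return isoforms


def aberrant_transcript_seq(iso: AberrantIsoform, model: GeneModel, genome) -> str:
    """Spliced sequence of the aberrant transcript (5'->3')."""
    exons = model.exons_transcript_order()
    parts: List[str] = []
    for i, (s, e) in enumerate(exons):
        if iso.kind == "exon_skip" and i == iso.skipped_exon:
            continue
        seq = get_seq(genome, model.scaffold, s, e)
        parts.append(seq if model.strand == "+" else revcomp(seq))
        if iso.kind == "intron_retention" and i == iso.disrupted_intron:
            parts.append(model.intron_seq(iso.disrupted_intron, genome)[: iso.retained_length])
    return "".join(parts)


def _aberrant_offset(iso: AberrantIsoform, model: GeneModel, gpos: int) -> Optional[int]:
    """Offset of an exonic genomic position in the aberrant transcript.

    None when the position falls in the skipped exon (or is not exonic).
    """
    exons = model.exons_transcript_order()
    offset = 0
    for i, (s, e) in enumerate(exons):
        if iso.kind == "exon_skip" and i == iso.skipped_exon:
            continue
        if s <= gpos < e:
            return offset + (gpos - s if model.strand == "+" else e - 1 - gpos)
        offset += e - s
        if iso.kind == "intron_retention" and i == iso.disrupted_intron:
            offset += iso.retained_length
    return None


def _cds_base_genomic(model: GeneModel, k: int) -> int:
    """Genomic coordinate of the k-th spliced CDS base (transcript order)."""
    blocks = model.cds if model.strand == "+" else list(reversed(model.cds))
    for s, e in blocks:
        n = e - s
        if k < n:
            return s + k if model.strand == "+" else e - 1 - k
        k -= n
    raise ValidationError("CDS offset out of range")


def translate_isoform(
    iso: AberrantIsoform, model: GeneModel, genome
) -> TranslationResult:
    """Translate an aberrant transcript from the reference start codon.

    Translation runs until the first stop codon or the transcript end
    (``runoff`` flagged).  If the modification removed the start codon
    (skipped exon containing it), a ``start_lost`` result with an empty
    protein is returned.  ``truncated`` means premature termination: the
    stop used is not the reference stop codon (an in-frame internal
    deletion that keeps the reference terminus is not a truncation).
    """
    start_g = model.cds_start_genomic()
    offset = _aberrant_offset(iso, model, start_g)
    if offset is None:
        return TranslationResult(protein="", stop_offset=None, start_lost=True, truncated=True)

    seq = aberrant_transcript_seq(iso, model, genome)
    coding = seq[offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    if not coding.startswith("ATG"):
        return TranslationResult(protein="", stop_offset=None, start_lost=True, truncated=True)
    protein_full = str(Seq(coding).translate())
    stop_at = protein_full.find("*")
    if stop_at == -1:
        return TranslationResult(
            protein=protein_full, stop_offset=None, runoff=True, truncated=True
        )
    protein = protein_full[:stop_at]
    stop_offset = offset + 3 * stop_at
    cds_len = sum(e - s for s, e in model.cds)
    ref_stop_g = _cds_base_genomic(model, cds_len - 3)
    ref_stop_offset = _aberrant_offset(iso, model, ref_stop_g)
    return TranslationResult(
        protein=protein,
        stop_offset=stop_offset,
        runoff=False,
        truncated=stop_offset != ref_stop_offset,
    )


@dataclass
class TruncationReport:
    lost: Tuple[str, ...]
    partial: Tuple[str, ...]
    retained: Tuple[str, ...]
    aberrant_length: int
    reference_length: int


def report_truncation(
    protein: str, reference_protein: str, domains: DomainTable
) -> TruncationReport:
    """Classify each domain of the reference protein against a truncation.

    A domain is ``lost`` when it lies entirely beyond the aberrant protein
    (aa_start > L), ``partial`` when the truncation cuts through it
    (aa_start <= L < aa_end), and ``retained`` otherwise.
    """
    L = len(protein)
    lost, partial, retained = [], [], []
    for d in domains:
        if d.aa_start > L:
            lost.append(d.name)
        elif d.aa_end > L:
            partial.append(d.name)
        else:
            retained.append(d.name)
    return TruncationReport(
        lost=tuple(lost),
        partial=tuple(partial),
        retained=tuple(retained),
        aberrant_length=L,
        reference_length=len(reference_protein),
    )
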