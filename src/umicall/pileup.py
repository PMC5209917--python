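"""Barcode-resolved pileup construction and I/O.

Builds :class:`LocusPileup` objects — one per target base — either from a
coordinate-sorted, indexed BAM/SAM (with the molecular barcode in an
alignment tag or the read name) or from a plain-text fixture table.  Also
hosts the directional barcode-clustering step and the VCF writer.

Coordinate conventions: BED input is 0-based half-open; pileups, the fixture
table and VCF output are 1-based.  Conversion happens only at the I/O
boundary.

Allele tokens follow the samtools-pileup idiom: a single uppercase base for
an SNV/reference observation, ``+SEQ`` for an insertion of SEQ immediately
after the locus, ``-SEQ`` for a deletion of SEQ immediately after the locus
(both anchored at the preceding base, VCF-style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pysam

from .model import BarcodeFamily, LocusCall, ReadObservation

__all__ = [
    "LocusPileup",
    "BarcodeCluster",
    "BarcodeConfig",
    "extract_barcode",
    "levenshtein",
    "cluster_barcodes",
    "read_bed",
    "build_pileups",
    "read_pileup_table",
    "write_pileup_table",
    "write_vcf",
]

log = logging.getLogger("umicall")

PILEUP_COLUMNS = ("contig", "pos", "ref", "barcode", "allele", "phred_q", "strand", "pair_id")

#: Filter labels that may appear in VCF FILTER; declared in the header.
FILTER_LABELS = {
    "StrongBarcode": "Too few barcodes with strong per-barcode evidence",
    "StrandBias": "Variant barcodes significantly biased toward one strand",
    "Homopolymer": "Variant in or adjacent to a long single-base run",
    "LowComplexity": "Dinucleotide entropy of the surrounding window below floor",
    "Repeat": "Surrounding window dominated by a short tandem repeat",
}


@dataclass
class LocusPileup:
    """All barcode families covering one genomic position."""

    contig: str
    pos: int  # 1-based
    ref: str
    families: List[BarcodeFamily] = field(default_factory=list)

    @property
    def barcode_depth(self) -> int:
        return len(self.families)

    @property
    def read_depth(self) -> int:
        return sum(len(f) for f in self.families)

    @property
    def rpb(self) -> float:
        return self.read_depth / self.barcode_depth if self.families else 0.0


@dataclass
class BarcodeCluster:
    """A set of barcodes merged into the one with the most supporting reads."""

    representative: str
    members: Dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.members.values())


@dataclass(frozen=True)
class BarcodeConfig:
    """Where to find the molecular barcode on each read."""

    mode: str = "tag"  # "tag" | "name"
    tag: str = "MI"
    fallback_tag: str = "BX"
    delimiter: str = ":"


def extract_barcode(read: "pysam.AlignedSegment", config: BarcodeConfig = BarcodeConfig()) -> Optional[str]:
    """Pull the barcode off an aligned record; ``None`` marks a barcode-less read."""
    try:
        if config.mode == "tag":
            for tag in (config.tag, config.fallback_tag):
                if read.has_tag(tag):
                    value = str(read.get_tag(tag)).strip().upper()
                    return value or None
            return None
        if config.mode == "name":
            name = read.query_name or ""
            if config.delimiter not in name:
                return None
            value = name.rsplit(config.delimiter, 1)[1].strip().upper()
            return value or None
        raise ValueError(f"unknown barcode mode {config.mode!r}")
    except ValueError:
        raise
    except Exception:  # malformed record: skip, never abort
        log.warning("could not extract barcode from record %r", getattr(read, "query_name", "?"))
        return None


def levenshtein(a: str, b: str, limit: Optional[int] = None) -> int:
    """Levenshtein edit distance with an optional early-exit band.

    Barcodes are short (8-12 nt) so a plain O(len(a)*len(b)) DP is fine; with
    ``limit`` set, returns ``limit + 1`` as soon as the distance provably
    exceeds it.
    """
    if a == b:
        return 0
    if limit is not None and abs(len(a) - len(b)) > limit:
        return limit + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        best = i
        for j, cb in enumerate(b, 1):
            cost = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            cur.append(cost)
            best = min(best, cost)
        if limit is not None and best > limit:
            return limit + 1
        prev = cur
    return prev[-1]


def cluster_barcodes(
    counts: Dict[str, int],
    max_edit_distance: int = 1,
) -> List[BarcodeCluster]:
    """Directional merging of near-identical barcodes.

    Barcodes within ``max_edit_distance`` are merged into the higher-count
    barcode when ``count_major >= 2 * count_minor - 1``; merging proceeds
    transitively outward from the highest-count seed, so sequencing errors of
    errors still collapse onto the true barcode.  Total read count is
    conserved and the number of barcodes never increases.
    """
    if not counts:
        raise ValueError("cluster_barcodes requires a non-empty count map")
    order = sorted(counts, key=lambda b: (-counts[b], b))
    assigned: Dict[str, str] = {}
    clusters: List[BarcodeCluster] = []
    for seed in order:
        if seed in assigned:
            continue
        members = {seed: counts[seed]}
        assigned[seed] = seed
        queue = [seed]
        while queue:
            u = queue.pop()
            for v in order:
                if v in assigned:
                    continue
                if counts[u] < 2 * counts[v] - 1:
                    continue
                if levenshtein(u, v, max_edit_distance) <= max_edit_distance:
                    assigned[v] = seed
                    members[v] = counts[v]
                    queue.append(v)
        clusters.append(BarcodeCluster(representative=seed, members=members))
    return clusters


def read_bed(path: str) -> List[Tuple[str, int, int]]:
    """Minimal BED reader: (contig, start, end), 0-based half-open."""
    regions: List[Tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            regions.append((parts[0], int(parts[1]), int(parts[2])))
    return regions


def _read_observations(
    read: "pysam.AlignedSegment",
    start: int,
    end: int,
    ref_seq: str,
    ref_offset: int,
    min_baseq: int,
) -> Iterator[Tuple[int, str, int]]:
    """Yield (0-based ref position, allele token, phred) for one read.

    Walks the CIGAR once; emits SNV observations for aligned bases within
    [start, end) and indel tokens anchored at the base preceding the event.
    Ambiguous (N) bases and events anchored outside the window are skipped.
    """
    qseq = read.query_sequence
    quals = read.query_qualities
    if qseq is None or quals is None:
        return
    calls: Dict[int, Tuple[str, int]] = {}
    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            for k in range(length):
                p = rpos + k
                if start <= p < end:
                    base = qseq[qpos + k].upper()
                    q = quals[qpos + k]
                    if base in "ACGT" and q >= min_baseq:
                        calls[p] = (base, q)
            qpos += length
            rpos += length
        elif op == 1:  # insertion: replaces the anchor-base call of this read
            anchor = rpos - 1
            if start <= anchor < end:
                seq = qseq[qpos : qpos + length].upper()
                q = min(quals[qpos : qpos + length])
                if "N" not in seq and q >= min_baseq:
                    calls[anchor] = ("+" + seq, q)
                else:
                    calls.pop(anchor, None)
            qpos += length
        elif op == 2:  # deletion: replaces the anchor-base call of this read
            anchor = rpos - 1
            if start <= anchor < end:
                seq = ref_seq[rpos - ref_offset : rpos - ref_offset + length].upper()
                q = quals[qpos - 1] if qpos > 0 else 0
                if q >= min_baseq:
                    calls[anchor] = ("-" + seq, q)
                else:
                    calls.pop(anchor, None)
            rpos += length
        elif op == 3:  # N (skip)
            rpos += length
        elif op == 4:  # soft clip
            qpos += length
        # H/P consume nothing
    for p in sorted(calls):
        allele, q = calls[p]
        yield p, allele, q


def build_pileups(
    alignments: str,
    targets: str,
    reference,
    filter_config=None,
    barcode_config: BarcodeConfig = BarcodeConfig(),
    max_edit_distance: int = 1,
    primer_bed: Optional[str] = None,
) -> Iterator[LocusPileup]:
    """Stream one :class:`LocusPileup` per target base, in genomic order.

    ``alignments`` is a coordinate-sorted, indexed BAM (or SAM with index);
    ``reference`` is a FASTA path or an object with ``fetch(contig, start,
    end)``.  Read-level pre-filters are applied before family formation and
    barcode clustering is applied per target region.  Bases falling in
    ``primer_bed`` intervals are excluded from evidence.
    """
    from .filters import FilterConfig, prefilter_read

    cfg = filter_config or FilterConfig()
    if isinstance(reference, str):
        from pyfaidx import Fasta

        reference = Fasta(reference, as_raw=True, sequence_always_upper=True)

    regions = read_bed(targets)
    primer_mask: Dict[str, set] = {}
    if primer_bed:
        for contig, s, e in read_bed(primer_bed):
            primer_mask.setdefault(contig, set()).update(range(s, e))

    with pysam.AlignmentFile(alignments) as bam:
        bam_contigs = set(bam.references)
        for contig, start, end in regions:
            if contig not in bam_contigs:
                raise ValueError(
                    f"target contig {contig!r} absent from alignment file {alignments!r}"
                )
            try:
                ref_seq = str(reference.fetch(contig, start, end + 1000))
            except AttributeError:
                ref_seq = str(reference[contig][start : end + 1000])
            # per position: barcode -> pair_id -> list[(allele, q, strand)]
            per_pos: Dict[int, Dict[str, Dict[str, List[Tuple[str, int, str]]]]] = {}
            barcode_reads: Dict[str, set] = {}
            n_barcodeless = 0
            for read in bam.fetch(contig, start, end):
                ok, _reason = prefilter_read(read, cfg)
                if not ok:
                    continue
                barcode = extract_barcode(read, barcode_config)
                if barcode is None:
                    n_barcodeless += 1
                    continue
                strand = "-" if read.is_reverse else "+"
                pair_id = read.query_name or ""
                barcode_reads.setdefault(barcode, set()).add(pair_id)
                for p, allele, q in _read_observations(
                    read, start, end, ref_seq, start, cfg.min_baseq
                ):
                    if contig in primer_mask and p in primer_mask[contig]:
                        continue
                    per_pos.setdefault(p, {}).setdefault(barcode, {}).setdefault(
                        pair_id, []
                    ).append((allele, q, strand))
            if n_barcodeless:
                log.info(
                    "%s:%d-%d: %d reads without a barcode excluded",
                    contig, start, end, n_barcodeless,
                )

            # cluster barcodes on read-pair counts within the region
            rename: Dict[str, str] = {}
            if barcode_reads:
                counts = {bc: len(pairs) for bc, pairs in barcode_reads.items()}
                for cluster in cluster_barcodes(counts, max_edit_distance):
                    for member in cluster.members:
                        rename[member] = cluster.representative

            for p in range(start, end):
                families: Dict[str, BarcodeFamily] = {}
                for barcode, pairs in per_pos.get(p, {}).items():
                    rep = rename.get(barcode, barcode)
                    fam = families.setdefault(rep, BarcodeFamily(barcode=rep))
                    for pair_id, calls in pairs.items():
                        obs = _consolidate_mates(calls, pair_id)
                        if obs is not None:
                            fam.observations.append(obs)
                fams = [f for f in families.values() if len(f) > 0]
                fams.sort(key=lambda f: f.barcode)
                yield LocusPileup(
                    contig=contig,
                    pos=p + 1,
                    ref=ref_seq[p - start],
                    families=fams,
                )


def _consolidate_mates(
    calls: Sequence[Tuple[str, int, str]], pair_id: str
) -> Optional[ReadObservation]:
    """One vote per read pair: agreeing mates keep the higher quality,
    disagreeing mates are discarded."""
    if not calls:
        return None
    alleles = {c[0] for c in calls}
    if len(alleles) > 1:
        return None
    allele, q, strand = max(calls, key=lambda c: c[1])
    return ReadObservation(allele=allele, phred_q=q, strand=strand, pair_id=pair_id)


def write_pileup_table(pileups: Iterable[LocusPileup], path: str) -> None:
    """Write the tab-separated fixture format (columns: see PILEUP_COLUMNS)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PILEUP_COLUMNS) + "\n")
        for pu in pileups:
            for fam in pu.families:
                for obs in fam.observations:
                    fh.write(
                        f"{pu.contig}\t{pu.pos}\t{pu.ref}\t{fam.barcode}\t"
                        f"{obs.allele}\t{obs.phred_q}\t{obs.strand}\t{obs.pair_id}\n"
                    )


def read_pileup_table(path: str) -> Iterator[LocusPileup]:
    """Stream pileups back from the fixture table; positions must be sorted."""
    current: Optional[LocusPileup] = None
    fam_index: Dict[str, BarcodeFamily] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(PILEUP_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(PILEUP_COLUMNS)} columns, got {len(parts)}"
                )
            contig, pos_s, ref, barcode, allele, q_s, strand, pair_id = parts
            try:
                pos, q = int(pos_s), int(q_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if current is None or (current.contig, current.pos) != (contig, pos):
                if (
                    current is not None
                    and contig == current.contig
                    and pos <= current.pos
                ):
                    raise ValueError(
                        f"{path}:{lineno}: positions out of order at {contig}:{pos}"
                    )
                if current is not None:
                    current.families.sort(key=lambda f: f.barcode)
                    yield current
                current = LocusPileup(contig=contig, pos=pos, ref=ref)
                fam_index = {}
            fam = fam_index.get(barcode)
            if fam is None:
                fam = BarcodeFamily(barcode=barcode)
                fam_index[barcode] = fam
                current.families.append(fam)
            fam.observations.append(
                ReadObservation(allele=allele, phred_q=q, strand=strand, pair_id=pair_id)
            )
    if current is not None:
        current.families.sort(key=lambda f: f.barcode)
        yield current


def _vcf_alleles(ref_base: str, allele: str) -> Tuple[str, str]:
    """Pileup-style allele token to VCF (REF, ALT) at the anchor base."""
    if allele.startswith("+"):
        return ref_base, ref_base + allele[1:]
    if allele.startswith("-"):
        return ref_base + allele[1:], ref_base
    return ref_base, allele


def write_vcf(
    calls: Iterable[LocusCall],
    path: str,
    sample: str = "SAMPLE",
    contigs: Optional[Dict[str, int]] = None,
    emit_date: bool = True,
) -> int:
    """Write candidate calls as VCF 4.2; returns the number of records.

    QUAL is the prediction index of the best alternative allele; INFO carries
    barcode depth (UMT), alternative barcode count (VMT), alternative barcode
    fraction (VMF) and mean read pairs per barcode (RPB).  Failed
    post-filters appear in FILTER; a filter-free candidate is PASS.
    """
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    if emit_date:
        import datetime

        header.add_line(f"##fileDate={datetime.date.today():%Y%m%d}")
    header.add_line("##source=umicall")
    for name, desc in FILTER_LABELS.items():
        header.add_meta("FILTER", items=[("ID", name), ("Description", desc)])
    header.add_meta("INFO", items=[("ID", "UMT"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "Total barcode (molecule) depth")])
    header.add_meta("INFO", items=[("ID", "VMT"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "Barcodes whose consensus is the ALT allele")])
    header.add_meta("INFO", items=[("ID", "VMF"), ("Number", 1), ("Type", "Float"),
                                   ("Description", "ALT barcode fraction VMT/UMT")])
    header.add_meta("INFO", items=[("ID", "RPB"), ("Number", 1), ("Type", "Float"),
                                   ("Description", "Mean read pairs per barcode at the locus")])
    header.add_meta("INFO", items=[("ID", "PI"), ("Number", 1), ("Type", "Float"),
                                   ("Description", "Prediction index of the ALT allele")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", 1), ("Type", "String"),
                                     ("Description", "Genotype")])
    contigs = dict(contigs or {})
    calls = list(calls)
    for call in calls:
        if call.contig not in contigs:
            contigs[call.contig] = max(
                (c.pos for c in calls if c.contig == call.contig), default=0
            ) + 1000
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_sample(sample)

    n = 0
    prev: Optional[Tuple[str, int]] = None
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in calls:
            if prev is not None and prev[0] == call.contig and call.pos < prev[1]:
                raise ValueError(
                    f"calls not in genomic order at {call.contig}:{call.pos}"
                )
            prev = (call.contig, call.pos)
            if not call.candidate_alleles:
                continue
            best = call.best_candidate()
            ref, alt = _vcf_alleles(call.reference, best)
            rec = out.new_record(
                contig=call.contig,
                start=call.pos - 1,
                alleles=(ref, alt),
                qual=round(call.prediction_index[best], 4),
            )
            if call.filters:
                for f in call.filters:
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            vmt = call.consensus_counts.get(best, 0)
            rec.info["UMT"] = call.n_barcodes
            rec.info["VMT"] = vmt
            rec.info["VMF"] = round(vmt / call.n_barcodes, 6) if call.n_barcodes else 0.0
            rec.info["RPB"] = round(call.rpb, 4)
            rec.info["PI"] = round(call.prediction_index[best], 4)
            rec.samples[sample]["GT"] = (0, 1)
            out.write(rec)
            n += 1
    return n
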