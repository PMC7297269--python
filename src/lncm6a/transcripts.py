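"""Transcript exon models, coordinate projection and region queries.

Two coordinate modes are supported throughout the package:

* ``full_transcript`` — positions on the unspliced pre-RNA (introns
  included), 1-based from the transcript's 5' end.
* ``mature_rna`` — positions on the spliced transcript (exons only),
  1-based from the 5' end.

Genomic coordinates are 1-based inclusive (GTF convention) internally;
BED output elsewhere is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import gffutils

log = logging.getLogger(__name__)

SJ_DISTANCE_CAP = 2000  # nt; from the dist_sj_*_p2000 feature definition


class Mode(str, Enum):
    FULL = "full_transcript"
    MATURE = "mature_rna"


def _as_mode(mode) -> "Mode":
    return Mode(mode)


@dataclass
class TranscriptModel:
    """Exon structure of one transcript.

    ``exons`` are genomic 1-based inclusive intervals, stored sorted by
    genomic start; transcript orientation (5'->3') follows ``strand``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ex = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping exons in {self.transcript_id}: "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        self.exons = ex

    # --- lengths -----------------------------------------------------
    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def full_length(self) -> int:
        s, e = self.span
        return e - s + 1

    @property
    def mature_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def length(self, mode) -> int:
        return self.full_length if _as_mode(mode) is Mode.FULL else self.mature_length

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_5p_to_3p(self) -> list[tuple[int, int]]:
        """Exons ordered in transcript orientation."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    # --- projection --------------------------------------------------
    def genomic_to_transcript(self, gpos: int, mode) -> int:
        mode = _as_mode(mode)
        s, e = self.span
        if mode is Mode.FULL:
            if not s <= gpos <= e:
                raise ValueError(f"genomic {gpos} outside span [{s},{e}]")
            return gpos - s + 1 if self.strand == "+" else e - gpos + 1
        offset = 0
        for xs, xe in self.exons_5p_to_3p():
            if xs <= gpos <= xe:
                within = (gpos - xs) if self.strand == "+" else (xe - gpos)
                return offset + within + 1
            offset += xe - xs + 1
        if s <= gpos <= e:
            raise ValueError(f"genomic {gpos} is intronic: no mature image")
        raise ValueError(f"genomic {gpos} outside span [{s},{e}]")

    def transcript_to_genomic(self, tpos: int, mode) -> int:
        mode = _as_mode(mode)
        n = self.length(mode)
        if not 1 <= tpos <= n:
            raise ValueError(f"transcript position {tpos} outside [1,{n}]")
        s, e = self.span
        if mode is Mode.FULL:
            return s + tpos - 1 if self.strand == "+" else e - tpos + 1
        offset = 0
        for xs, xe in self.exons_5p_to_3p():
            ln = xe - xs + 1
            if tpos <= offset + ln:
                within = tpos - offset - 1
                return xs + within if self.strand == "+" else xe - within
            offset += ln
        raise AssertionError("unreachable")

    # --- region structure in transcript coordinates ------------------
    def blocks(self, mode) -> list[tuple[int, int, str, int]]:
        """(start, end, kind, exon_rank) blocks in mode coordinates, 5'->3'.

        kind is 'exon' or 'intron'; exon_rank counts exons from the 5'
        end (1-based), -1 for introns.  In mature mode every block is an
        exon and positions are contiguous spliced coordinates.
        """
        mode = _as_mode(mode)
        out = []
        pos = 1
        exons = self.exons_5p_to_3p()
        for rank, (xs, xe) in enumerate(exons, start=1):
            ln = xe - xs + 1
            out.append((pos, pos + ln - 1, "exon", rank))
            pos += ln
            if mode is Mode.FULL and rank < len(exons):
                nxt = exons[rank]
                gap = (nxt[0] - xe - 1) if self.strand == "+" else (xs - nxt[1] - 1)
                if gap > 0:
                    out.append((pos, pos + gap - 1, "intron", -1))
                    pos += gap
        return out


def project(model: TranscriptModel, position: int, from_system: str,
            to_system: str, mode) -> int:
    """Project between 'genomic' and 'transcript' coordinate systems."""
    systems = {"genomic", "transcript"}
    if from_system not in systems or to_system not in systems:
        raise ValueError(f"coordinate systems must be one of {systems}")
    if from_system == to_system:
        return position
    if from_system == "genomic":
        return model.genomic_to_transcript(position, mode)
    return model.transcript_to_genomic(position, mode)


def splice_junction_distances(model: TranscriptModel, site: int, mode,
                              cap: int = SJ_DISTANCE_CAP) -> tuple[int, int]:
    """Distances (5', 3') to the nearest splice junctions, truncated at cap.

    A junction between transcript positions j|j+1 is addressed by j:
    dist_5' = site - j over junctions with j < site, dist_3' = j - site
    over junctions with j >= site.  Single-exon transcripts (no
    junctions) return (cap, cap).
    """
    n = model.length(mode)
    if not 1 <= site <= n:
        raise ValueError(f"site {site} off transcript (length {n})")
    junctions = [end for (start, end, kind, rank) in model.blocks(mode)[:-1]]
    if not junctions:
        return cap, cap
    up = [site - j for j in junctions if j < site]
    down = [j - site for j in junctions if j >= site]
    return (min(min(up), cap) if up else cap,
            min(min(down), cap) if down else cap)


REGION_FLAG_NAMES = [
    "exon",
    "intron",
    "first_exon",
    "internal_exon",
    "last_exon",
    "tx_5p_half",
    "tx_3p_half",
    "near_tss_100",
    "near_tes_100",
    "long_exon_400",
]


def region_flags(model: TranscriptModel, site: int, mode) -> list[int]:
    """The 10 binary topology dummies for a site (transcript coordinates).

    Flags: exon / intron overlap; first, internal and last exon; 5'- and
    3'-half of the transcript; within 100 nt of the transcription start /
    end; containing exon of length >= 400 nt.
    """
    mode = _as_mode(mode)
    n = model.length(mode)
    if not 1 <= site <= n:
        raise ValueError(f"site {site} off transcript (length {n})")
    block = next(b for b in model.blocks(mode) if b[0] <= site <= b[1])
    start, end, kind, rank = block
    in_exon = kind == "exon"
    n_ex = model.n_exons
    flags = {
        "exon": in_exon,
        "intron": not in_exon,
        "first_exon": in_exon and rank == 1,
        "internal_exon": in_exon and 1 < rank < n_ex,
        "last_exon": in_exon and rank == n_ex,
        "tx_5p_half": site <= n / 2,
        "tx_3p_half": site > n / 2,
        "near_tss_100": site <= 100,
        "near_tes_100": n - site < 100,
        "long_exon_400": in_exon and (end - start + 1) >= 400,
    }
    return [int(flags[name]) for name in REGION_FLAG_NAMES]


def containing_region_length(model: TranscriptModel, site: int, mode) -> int:
    """Length of the exon (or intron, full mode) containing the site."""
    for start, end, kind, rank in model.blocks(mode):
        if start <= site <= end:
            return end - start + 1
    raise ValueError(f"site {site} off transcript")


def select_longest_transcript(transcripts: list[TranscriptModel]) -> TranscriptModel:
    """Transcript with maximum mature length; ties -> smallest transcript_id."""
    if not transcripts:
        raise ValueError("gene has no transcripts")
    return min(transcripts, key=lambda t: (-t.mature_length, t.transcript_id))


def _exon_ids(feature, db) -> tuple[str, str]:
    """(gene_id, transcript_id) for an exon feature in GTF or GFF3 dialect."""
    attrs = feature.attributes
    gene = attrs.get("gene_id", [None])[0]
    tx = attrs.get("transcript_id", [None])[0]
    if tx is None and "Parent" in attrs:  # GFF3: exon -> transcript -> gene
        tx = attrs["Parent"][0]
        if gene is None:
            try:
                parent = db[tx]
                gene = (parent.attributes.get("gene_id", [None])[0]
                        or parent.attributes.get("Parent", [None])[0]
                        or parent.attributes.get("ID", [None])[0])
            except gffutils.FeatureNotFoundError:
                gene = None
    return gene, tx


def load_annotation(path) -> dict[str, list[TranscriptModel]]:
    """Parse a GTF or GFF3 file into transcript models grouped by gene.

    Only ``exon`` features are used; each must resolve a transcript_id
    and gene_id (GTF attributes, or GFF3 Parent links).
    """
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot parse annotation {path}: {exc}") from exc

    grouped: dict[tuple[str, str], dict] = {}
    for i, ex in enumerate(db.features_of_type("exon"), start=1):
        gene, tx = _exon_ids(ex, db)
        if gene is None or tx is None:
            raise ValueError(
                f"{path}: exon record #{i} lacks gene_id/transcript_id "
                f"(line {ex.start}-{ex.end} on {ex.seqid})"
            )
        key = (gene, tx)
        rec = grouped.setdefault(
            key, {"chrom": ex.seqid, "strand": ex.strand, "exons": []}
        )
        rec["exons"].append((ex.start, ex.end))

    genes: dict[str, list[TranscriptModel]] = {}
    for (gene, tx), rec in grouped.items():
        genes.setdefault(gene, []).append(
            TranscriptModel(tx, gene, rec["chrom"], rec["strand"], rec["exons"])
        )
    if not genes:
        log.warning("%s: no exon records found", path)
    for gene, txs in genes.items():
        txs.sort(key=lambda t: t.transcript_id)
    return genes
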