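"""Auxin-response-element (AuxRE) scanning of upstream regulatory regions.

The canonical AuxRE is the hexamer TGTCTC (reverse complement GAGACA);
its core is the tetramer TGTC (GACA).  Promoters are taken as a fixed
number of bases immediately 5' of the translation start on the coding
strand (3 kb by default).  All occurrences of the four motifs are
counted, overlaps included, and runs of core motifs within a small gap
are reported as tandem clusters.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import CoordinateError, InputError
from .io import GeneMeta

log = logging.getLogger("auxiaa")

CANONICAL_FWD = "TGTCTC"
CANONICAL_REV = "GAGACA"
CORE_FWD = "TGTC"
CORE_REV = "GACA"

MOTIFS = {
    "canonical_fwd": CANONICAL_FWD,
    "canonical_rev": CANONICAL_REV,
    "core_fwd": CORE_FWD,
    "core_rev": CORE_REV,
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NT_ALPHABET = set("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (alphabet ACGTN)."""
    bad = set(seq) - _NT_ALPHABET
    if bad:
        raise InputError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    motif: str          # canonical_fwd | canonical_rev | core_fwd | core_rev
    position: int       # 0-based offset in the promoter
    matched_text: str
    within_canonical: bool = False  # core hit contained in a canonical hit


@dataclass
class AuxREProfile:
    """Per-promoter AuxRE inventory: counts, positions, tandem clusters."""

    gene_id: str
    hits: list[MotifHit] = field(default_factory=list)
    tandem_clusters: list[tuple[int, int, int]] = field(default_factory=list)

    def count(self, motif: str) -> int:
        return sum(1 for h in self.hits if h.motif == motif)

    @property
    def counts(self) -> dict[str, int]:
        return {m: self.count(m) for m in MOTIFS}

    @property
    def has_canonical(self) -> bool:
        return self.count("canonical_fwd") + self.count("canonical_rev") > 0


def extract_promoter(
    gene: GeneMeta, chromosome_sequence: str, length: int = 3000
) -> tuple[str, str]:
    """Upstream regulatory region of a gene on its coding strand.

    For a plus-strand gene this is the ``length`` bases ending just
    before the annotated start; for a minus-strand gene the ``length``
    bases following the annotated end, reverse-complemented.  Truncated
    (with a warning) when the chromosome end intervenes.
    """
    n = len(chromosome_sequence)
    if not (1 <= gene.start <= gene.end <= n):
        raise CoordinateError(
            f"{gene.gene_name}: coordinates {gene.start}-{gene.end} outside "
            f"chromosome of length {n}"
        )
    if gene.strand == 1:
        hi = gene.start - 1            # 0-based, exclusive
        lo = max(0, hi - length)
        promoter = chromosome_sequence[lo:hi]
    else:
        lo = gene.end                  # 0-based, inclusive
        hi = min(n, lo + length)
        promoter = reverse_complement(chromosome_sequence[lo:hi])
    if len(promoter) < length:
        log.warning(
            "%s: promoter truncated to %d bp (requested %d)",
            gene.gene_name, len(promoter), length,
        )
    return gene.gene_name, promoter


def _find_all(seq: str, motif: str) -> list[int]:
    """All (overlapping) start positions of ``motif`` in ``seq``."""
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def scan_auxre(promoter: str, gene_id: str = "", tandem_max_gap: int = 50) -> AuxREProfile:
    """Profile all AuxRE occurrences in a promoter.

    Core hits that fall inside a canonical hit are flagged
    ``within_canonical`` but still counted in the core totals.
    """
    if not promoter:
        raise InputError("empty promoter sequence")
    canonical_ivs: list[tuple[int, int]] = []
    hits: list[MotifHit] = []
    for name in ("canonical_fwd", "canonical_rev"):
        motif = MOTIFS[name]
        for pos in _find_all(promoter, motif):
            hits.append(MotifHit(name, pos, motif))
            canonical_ivs.append((pos, pos + len(motif)))
    for name in ("core_fwd", "core_rev"):
        motif = MOTIFS[name]
        for pos in _find_all(promoter, motif):
            contained = any(a <= pos and pos + len(motif) <= b for a, b in canonical_ivs)
            hits.append(MotifHit(name, pos, motif, within_canonical=contained))
    hits.sort(key=lambda h: (h.position, h.motif))
    core_hits = [h for h in hits if h.motif.startswith("core")]
    return AuxREProfile(
        gene_id=gene_id,
        hits=hits,
        tandem_clusters=find_tandem_clusters(core_hits, max_gap=tandem_max_gap),
    )


def find_tandem_clusters(
    hits: list[MotifHit], max_gap: int = 50
) -> list[tuple[int, int, int]]:
    """Maximal runs of >=2 core hits with inter-start gaps <= ``max_gap``.

    Returns ``(start, end, n_copies)`` tuples, 0-based half-open over
    the promoter; clusters are non-overlapping by construction.
    """
    ordered = sorted(hits, key=lambda h: h.position)
    clusters: list[tuple[int, int, int]] = []
    run: list[MotifHit] = []
    for h in ordered:
        if run and h.position - run[-1].position <= max_gap:
            run.append(h)
        else:
            if len(run) >= 2:
                clusters.append(
                    (run[0].position, run[-1].position + len(run[-1].matched_text), len(run))
                )
            run = [h]
    if len(run) >= 2:
        clusters.append(
            (run[0].position, run[-1].position + len(run[-1].matched_text), len(run))
        )
    return clusters


def scan_promoters(
    promoters: list[tuple[str, str]], tandem_max_gap: int = 50
) -> list[AuxREProfile]:
    profiles = [scan_auxre(seq, gene_id=gid, tandem_max_gap=tandem_max_gap)
                for gid, seq in promoters]
    n_canon = sum(p.has_canonical for p in profiles)
    log.info("scanned %d promoters; %d contain a canonical AuxRE", len(profiles), n_canon)
    return profiles
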