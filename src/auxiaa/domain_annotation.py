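"""Domain architecture and motif annotation of Aux/IAA proteins.

Calls, per protein: spans of the four conserved domains (with
completeness and split flags), the domain-I repressor motif class
(LxLxLP or the LxLxPP variant), the GWPPV degron in domain II, the two
nuclear localization signals (bipartite KR-linker + basic hexamer, and
the C-terminal basic stretch at the end of domain IV), and the family
class A/B from the domain-III signature.

Detection is leftmost-match ungapped pattern scanning against the
profiles in :class:`auxiaa.config.PipelineConfig`; all decisions the
downstream analysis relies on are presence/absence and motif class, so
no alignment or HMM machinery is involved.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .config import DOMAIN_IDS, DomainProfile, PipelineConfig
from .errors import InputError

log = logging.getLogger("auxiaa")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

DEGRON = "GWPPV"
REPRESSOR_LXLXLP = re.compile(r"L.L.LP")
REPRESSOR_LXLXPP = re.compile(r"L.L.PP")


@dataclass(frozen=True)
class DomainSpan:
    """Residue span of one conserved domain, 0-based half-open."""

    domain_id: str
    start: int
    end: int
    complete: bool = True
    split: bool = False   # domain present in two parts (internal insertion)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise InputError(f"domain {self.domain_id}: bad span [{self.start},{self.end})")


@dataclass
class ProteinAnnotation:
    protein_id: str
    domains: dict[str, DomainSpan] = field(default_factory=dict)
    repressor_motif: str = "absent"      # LxLxLP | LxLxPP | absent
    degron_present: bool = False
    degron_position: int | None = None
    nls_bipartite: bool = False
    nls_cterminal: bool = False
    family_class: str = "unclassified"   # A | B | unclassified

    @property
    def canonical(self) -> bool:
        """All four domains present and complete."""
        return all(d in self.domains and self.domains[d].complete for d in DOMAIN_IDS)


def _check_protein(protein: str) -> None:
    if not protein:
        raise InputError("empty protein sequence")
    bad = set(protein) - AA_ALPHABET
    if bad:
        raise InputError(f"invalid residue characters: {sorted(bad)}")


def scan_domains(
    protein: str, profiles: dict[str, DomainProfile] | None = None
) -> dict[str, DomainSpan]:
    """Locate the four Aux/IAA domains in a protein sequence.

    For each domain the intact pattern is tried first (leftmost match);
    failing that, the two-part split pattern (ordered co-occurrence
    within the profile's gap limit, still complete); failing that, the
    truncated-remnant pattern (reported incomplete).  At most one span
    per domain is returned.
    """
    if profiles is None:
        profiles = PipelineConfig().domain_profiles
    _check_protein(protein)
    spans: dict[str, DomainSpan] = {}
    for dom, prof in profiles.items():
        m = re.search(prof.full, protein)
        if m:
            spans[dom] = DomainSpan(dom, m.start(), m.end())
            continue
        if prof.split_parts is not None:
            ma = re.search(prof.split_parts[0], protein)
            if ma:
                mb = re.compile(prof.split_parts[1]).search(protein, ma.end())
                if mb and mb.start() - ma.end() <= prof.split_max_gap:
                    spans[dom] = DomainSpan(dom, ma.start(), mb.end(), complete=True, split=True)
                    continue
        if prof.partial is not None:
            m = re.search(prof.partial, protein)
            if m:
                spans[dom] = DomainSpan(dom, m.start(), m.end(), complete=False)
    return spans


def classify_repressor_motif(protein: str, domain_i: DomainSpan | None) -> str:
    """Class of the domain-I repressor motif.

    ``LxLxLP`` when that pattern occurs within domain I (whole sequence
    when no span is given); ``LxLxPP`` when only the variant occurs;
    ``absent`` otherwise.
    """
    region = protein[domain_i.start : domain_i.end] if domain_i is not None else protein
    if REPRESSOR_LXLXLP.search(region):
        return "LxLxLP"
    if REPRESSOR_LXLXPP.search(region):
        return "LxLxPP"
    return "absent"


def detect_degron(protein: str, domain_ii: DomainSpan | None) -> tuple[bool, int | None]:
    """First occurrence of the GWPPV degron, restricted to domain II
    when a span is provided.  Returns ``(present, position)`` with the
    position on the whole-protein scale."""
    if domain_ii is not None:
        # str.find with bounds requires the motif to lie fully inside the span
        idx = protein.find(DEGRON, domain_ii.start, domain_ii.end)
    else:
        idx = protein.find(DEGRON)
    return (idx != -1, idx if idx != -1 else None)


def detect_nls(
    protein: str,
    domains: dict[str, DomainSpan],
    *,
    hexamer_pattern: str = r"[KR]{6}",
    cterm_pattern: str = r"[KR]{4}",
    cterm_window: int = 6,
) -> tuple[bool, bool]:
    """Detect the two Aux/IAA nuclear localization signals.

    Bipartite NLS: the dipeptide ``KR`` strictly between the end of
    domain I and the start of domain II, plus a basic hexamer inside
    domain II.  C-terminal NLS: a basic-residue stretch within the last
    ``cterm_window`` residues of domain IV.  A missing domain makes the
    corresponding signal False.
    """
    d1, d2, d4 = domains.get("I"), domains.get("II"), domains.get("IV")
    bipartite = False
    if d1 is not None and d2 is not None and d1.end < d2.start:
        linker = protein[d1.end : d2.start]
        if "KR" in linker and re.search(hexamer_pattern, protein[d2.start : d2.end]):
            bipartite = True
    cterminal = False
    if d4 is not None:
        tail = protein[max(d4.start, d4.end - cterm_window) : d4.end]
        if re.search(cterm_pattern, tail):
            cterminal = True
    return bipartite, cterminal


def assign_family_class(
    domain_iii_seq: str | None,
    class_signatures: dict[str, str] | None = None,
) -> str:
    """Assign class A or B from the domain-III signature.

    The two consensus signatures must be non-overlapping; ambiguous
    (both) or signature-free domain IIIs are ``unclassified``, as is a
    missing domain III.
    """
    if class_signatures is None:
        class_signatures = PipelineConfig().class_signatures
    if domain_iii_seq is None:
        log.warning("family class requested without a domain III span")
        return "unclassified"
    matches = [cls for cls, sig in sorted(class_signatures.items())
               if re.search(sig, domain_iii_seq)]
    return matches[0] if len(matches) == 1 else "unclassified"


def annotate_protein(protein_id: str, protein: str, config: PipelineConfig | None = None) -> ProteinAnnotation:
    """Full annotation of one protein (domains, motifs, NLS, class)."""
    config = config or PipelineConfig()
    domains = scan_domains(protein, config.domain_profiles)
    d3 = domains.get("III")
    degron_present, degron_pos = detect_degron(protein, domains.get("II"))
    if domains.get("II") is None:
        # degron lives in domain II; without the domain it cannot be functional
        degron_present, degron_pos = False, None
    bip, cterm = detect_nls(
        protein,
        domains,
        hexamer_pattern=config.nls_hexamer_pattern,
        cterm_pattern=config.nls_cterm_pattern,
        cterm_window=config.nls_cterm_window,
    )
    return ProteinAnnotation(
        protein_id=protein_id,
        domains=domains,
        repressor_motif=classify_repressor_motif(protein, domains.get("I")),
        degron_present=degron_present,
        degron_position=degron_pos,
        nls_bipartite=bip,
        nls_cterminal=cterm,
        family_class=assign_family_class(
            protein[d3.start : d3.end] if d3 is not None else None,
            config.class_signatures,
        ),
    )


def annotate_all(
    records: list[tuple[str, str]], config: PipelineConfig | None = None
) -> list[ProteinAnnotation]:
    anns = [annotate_protein(pid, seq, config) for pid, seq in records]
    log.info("annotated %d proteins (%d canonical)", len(anns), sum(a.canonical for a in anns))
    return anns


def annotation_table(annotations: list[ProteinAnnotation]) -> pd.DataFrame:
    """One row per protein with all annotation fields, for report output."""
    rows = []
    for a in annotations:
        row: dict = {
            "protein_id": a.protein_id,
            "repressor_motif": a.repressor_motif,
            "degron_present": a.degron_present,
            "degron_position": a.degron_position,
            "nls_bipartite": a.nls_bipartite,
            "nls_cterminal": a.nls_cterminal,
            "family_class": a.family_class,
            "canonical": a.canonical,
        }
        for dom in DOMAIN_IDS:
            span = a.domains.get(dom)
            row[f"domain_{dom}_start"] = span.start if span else None
            row[f"domain_{dom}_end"] = span.end if span else None
            row[f"domain_{dom}_complete"] = span.complete if span else False
            row[f"domain_{dom}_split"] = span.split if span else False
        rows.append(row)
    return pd.DataFrame(rows)
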