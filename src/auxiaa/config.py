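"""Pipeline configuration and default motif/domain pattern sets.

The Aux/IAA repressors carry four conserved domains (I-IV).  Domain
detection here is configurable ungapped pattern matching: each domain
profile anchors on conserved flanking blocks with a wildcard interior,
so presence/absence, completeness and split architectures can be called
without a profile HMM.  The shipped default patterns correspond to the
synthetic domain templates used by :mod:`auxiaa.synthetic_data`, which
keeps planted ground truth exactly recoverable; for real protein sets
the patterns are meant to be replaced in the config file.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ValidationError

DOMAIN_IDS = ("I", "II", "III", "IV")

#: Root-type expression hierarchy reported for the maize family
#: (shoot-borne crown roots highest, lateral roots lowest).
DEFAULT_ROOT_TYPE_ORDER = ("crown", "seminal", "primary", "lateral")


@dataclass(frozen=True)
class DomainProfile:
    """Ungapped pattern set describing one Aux/IAA domain.

    ``full`` matches the intact domain; ``split_parts`` (optional) are
    two sub-patterns whose ordered co-occurrence within ``split_max_gap``
    residues calls a domain interrupted by an insertion (still counted
    as complete, as for the nine-residue insertion in domain IV of
    ZmIAA28); ``partial`` (optional) matches a truncated remnant and is
    reported with ``complete=False``.
    """

    domain_id: str
    full: str
    split_parts: tuple[str, str] | None = None
    split_max_gap: int = 15
    partial: str | None = None


# Default synthetic domain templates (see synthetic_data):
#   I   : TE <6-aa repressor motif slot> GSEE
#   II  : KAQ <5-aa degron slot> IV <6-aa NLS hexamer slot> FD
#   III : GFS <8-aa class signature slot> LDL
#   IV  : PWN <7-aa core> <4-aa C-terminal NLS slot> EM
DEFAULT_DOMAIN_PROFILES: dict[str, DomainProfile] = {
    "I": DomainProfile("I", full=r"TE[A-Z]{6}GSEE"),
    "II": DomainProfile("II", full=r"KAQ[A-Z]{5}IV[A-Z]{6}FD"),
    "III": DomainProfile("III", full=r"GFS[A-Z]{8}LDL", partial=r"GFS[A-Z]{4}"),
    "IV": DomainProfile(
        "IV",
        full=r"PWN[A-Z]{11}EM",
        split_parts=(r"PWN[A-Z]{4}", r"[A-Z]{7}EM"),
        split_max_gap=15,
        partial=r"PWN[A-Z]{4}",
    ),
}

#: Domain III consensus signatures separating family class A from class B.
#: The class split coincides with a variant domain III sequence; by the
#: package's convention the variant signature is class B (configurable).
DEFAULT_CLASS_SIGNATURES: dict[str, str] = {
    "A": r"KAFEH[IV]LT",
    "B": r"RGWEH[CS]MS",
}

#: Bipartite NLS = "KR" linker between domains I and II plus a basic
#: hexamer inside domain II; second NLS = basic stretch in the last
#: ``nls_cterm_window`` residues of domain IV.
DEFAULT_NLS_HEXAMER_PATTERN = r"[KR]{6}"
DEFAULT_NLS_CTERM_PATTERN = r"[KR]{4}"


@dataclass
class PipelineConfig:
    """Run-wide settings shared by all pipeline stages.

    alpha_tiers
        Descending significance thresholds for the tiered pairwise
        t-test calls (default 0.05 / 0.01 / 0.001).
    bootstrap_n
        Phylogeny bootstrap replicate count (default 1,000).
    promoter_length
        Upstream region scanned for auxin-response elements, in bp
        (default 3,000 upstream of the ATG).
    housekeeping_gene
        Reference transcript for relative quantification (myosin).
    root_type_order
        Expected expression ranking of root types, highest first.
    """

    alpha_tiers: tuple[float, float, float] = (0.05, 0.01, 0.001)
    bootstrap_n: int = 1000
    promoter_length: int = 3000
    rng_seed: int = 0
    housekeeping_gene: str = "myosin"
    root_type_order: tuple[str, ...] = DEFAULT_ROOT_TYPE_ORDER

    # qRT-PCR
    max_ct: float = 35.0              # censoring threshold, cycles
    induction_alpha: float = 0.05     # per-comparison level for kinetics calls
    pooled_variance: bool = True      # classical Student (paper's test); False = Welch

    # promoter scanning
    tandem_max_gap: int = 50          # bp between core-motif starts in a cluster

    # phylogeny
    min_pair_support: float = 50.0    # % bootstrap needed to suggest a paralog pair

    # correlation
    r2_threshold: float = 0.5
    correlation_alpha: float = 0.01

    # annotation patterns
    domain_profiles: dict[str, DomainProfile] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_PROFILES)
    )
    class_signatures: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIGNATURES)
    )
    nls_hexamer_pattern: str = DEFAULT_NLS_HEXAMER_PATTERN
    nls_cterm_pattern: str = DEFAULT_NLS_CTERM_PATTERN
    nls_cterm_window: int = 6
    variant_domain3_class: str = "B"

    def __post_init__(self) -> None:
        tiers = tuple(self.alpha_tiers)
        if len(tiers) != 3 or any(not (0 < a < 1) for a in tiers):
            raise ValidationError(f"alpha_tiers must be three values in (0,1): {tiers}")
        if not (tiers[0] > tiers[1] > tiers[2]):
            raise ValidationError(f"alpha_tiers must be strictly decreasing: {tiers}")
        if self.promoter_length <= 0:
            raise ValidationError("promoter_length must be positive")
        order = tuple(self.root_type_order)
        if len(set(order)) != len(order):
            raise ValidationError(f"root_type_order has duplicates: {order}")
        self.alpha_tiers = tiers
        self.root_type_order = order

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "domain_profiles" in kwargs:
            profiles = {}
            for dom, spec in kwargs["domain_profiles"].items():
                spec = dict(spec)
                if spec.get("split_parts") is not None:
                    spec["split_parts"] = tuple(spec["split_parts"])
                profiles[dom] = DomainProfile(domain_id=dom, **spec)
            kwargs["domain_profiles"] = profiles
        if "alpha_tiers" in kwargs:
            kwargs["alpha_tiers"] = tuple(kwargs["alpha_tiers"])
        if "root_type_order" in kwargs:
            kwargs["root_type_order"] = tuple(kwargs["root_type_order"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["alpha_tiers"] = list(self.alpha_tiers)
        out["root_type_order"] = list(self.root_type_order)
        out["domain_profiles"] = {}
        for dom, prof in self.domain_profiles.items():
            spec = {k: v for k, v in asdict(prof).items()
                    if k != "domain_id" and v is not None}
            if "split_parts" in spec:
                spec["split_parts"] = list(spec["split_parts"])
            out["domain_profiles"][dom] = spec
        return out
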