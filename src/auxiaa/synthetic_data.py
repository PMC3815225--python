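"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design around the maize Aux/IAA
family: a 34-gene family with 29 canonical four-domain proteins and the
five known defective architectures, five LxLxPP repressor variants, 13
variant (class B) domain IIIs, seven retained duplicate (paralog)
pairs, promoters of which 28 carry canonical AuxRE hexamers and all
carry tandem core-motif runs; Ct tables with five biological x three
technical replicates under an exponential amplification model; and
auxin-induction time courses with planted sustained (A), transient (B)
or flat kinetics in three biological replicates.

Domain sequences are synthetic templates, not real ZmIAA sequences; the
only literature-derived fixture in the package is the gene-metadata
table.  All filler sequence is rejection-sampled (or repaired) to be
free of planted motifs, so count assertions against the truth are
exact, and every generator is a pure function of its parameters and
seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .induction_kinetics import TIME_POINTS, InductionSeries
from .qpcr_quant import DILUTION_SERIES

log = logging.getLogger("auxiaa")

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"

# ---------------------------------------------------------------------------
# domain templates (must stay in sync with config.DEFAULT_DOMAIN_PROFILES)

D1_FLANKS = ("TE", "GSEE")            # 6-aa repressor slot inside
D2_FLANKS = ("KAQ", "IV", "FD")       # 5-aa degron slot, 6-aa NLS hexamer slot
D3_FLANKS = ("GFS", "LDL")            # 8-aa class signature slot
D4_FLANKS = ("PWN", "EM")             # 7-aa core + 4-aa C-terminal NLS slot

REPRESSOR_SLOT = {"LxLxLP": "LRLGLP", "LxLxPP": "LALAPP", "absent": "AQSGTN"}
DEGRON_SLOT = {True: "GWPPV", False: "GAPAV"}
HEXAMER_SLOT = {True: "KRKRRK", False: "QSTNAG"}
CTERM_NLS_SLOT = {True: "KKRK", False: "QSTA"}
CLASS_SIGNATURE = {"A": "KAFEHVLT", "B": "RGWEHCMS"}

LINKER_LENS = (10, 8, 8, 8, 10)       # N-term, I-II, II-III, III-IV, C-term
SPLIT_INSERTION_LEN = 9               # residues inserted into a split domain IV

#: First alignment column of the split-IV insertion block
#: (l0 + domain I + l1 + domain II + l2 + domain III + l3 + PWN-half).
_INSERTION_COL = 10 + 12 + 8 + 18 + 8 + 14 + 8 + 7

AUXRE_CANONICAL = "TGTCTC"
AUXRE_CORES = ("TGTC", "GACA")

#: Architecture defects planted by the default family plan, mirroring
#: the family's known composition (1-based member indices).
DEFAULT_NO_D1_D2 = {25}               # domains I+II lacking, III+IV incomplete
DEFAULT_NO_D2 = {24, 26}
DEFAULT_NO_D4 = {22, 31}
DEFAULT_SPLIT_D4 = {28}
DEFAULT_LXLXPP = {3, 9, 13, 24, 26}
DEFAULT_CLASS_B = {4, 6, 9, 11, 12, 16, 17, 18, 20, 23, 30, 33, 34}
DEFAULT_PARALOG_PAIRS = ((1, 8), (2, 14), (3, 13), (5, 27), (10, 29), (18, 30), (21, 28))
DEFAULT_NO_CANONICAL_AUXRE = {5, 11, 17, 23, 29, 33}

#: Treatment-metadata note: the original study protocol states a 5 mM aNAA
#: working solution in its methods text but 5 uM in its induction figure;
#: both values are carried in the fixture metadata, unresolved.
TREATMENT_METADATA = {
    "auxin": "alpha-naphthyl acetic acid (aNAA)",
    "concentration_methods": "5 mM",
    "concentration_figure": "5 uM",
    "duration_h": 3,
}


@dataclass
class GenePlan:
    """Planted architecture and promoter plan for one synthetic gene."""

    name: str
    domains: tuple[str, ...] = ("I", "II", "III", "IV")
    incomplete: tuple[str, ...] = ()
    split_iv: bool = False
    repressor: str = "LxLxLP"         # LxLxLP | LxLxPP | absent
    degron: bool = True
    nls_bipartite: bool = True
    nls_cterminal: bool = True
    family_class: str = "A"           # A | B (ignored without domain III signature)
    n_canonical_auxre: int = 1
    n_core_tandem: int = 3
    paralog_partner: str | None = None

    def __post_init__(self) -> None:
        if self.degron and "II" not in self.domains:
            raise ParameterError(f"{self.name}: degron planted without domain II")
        if self.nls_cterminal and "IV" not in self.domains:
            raise ParameterError(f"{self.name}: C-terminal NLS planted without domain IV")
        if self.nls_bipartite and not {"I", "II"} <= set(self.domains):
            raise ParameterError(f"{self.name}: bipartite NLS needs domains I and II")
        if self.split_iv and ("IV" not in self.domains or "IV" in self.incomplete):
            raise ParameterError(f"{self.name}: split domain IV needs a complete domain IV")

    @property
    def canonical(self) -> bool:
        return set(self.domains) == {"I", "II", "III", "IV"} and not self.incomplete


@dataclass
class SimulationTruth:
    """Planted ground truth, sufficient to recompute every expected
    stage result; serialized beside the generated fixtures."""

    rng_seed: int
    gene_plans: dict[str, dict] = field(default_factory=dict)
    concentrations: dict[str, dict[str, float]] = field(default_factory=dict)
    efficiencies: dict[str, float] = field(default_factory=dict)
    induction_labels: dict[str, str] = field(default_factory=dict)
    induction_effects: dict[str, float] = field(default_factory=dict)
    paralog_pairs: list[tuple[str, str]] = field(default_factory=list)
    promoter_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Ct tables

@dataclass(frozen=True)
class GroupSpec:
    """One sample group of the expression design."""

    name: str
    root_type: str | None = None
    stage: str | None = None
    treatment_time: int | None = None
    n_bio: int = 5


def simulate_ct_table(
    groups: list[GroupSpec],
    concentrations: dict[str, dict[str, float]],
    *,
    sigma_bio: float = 0.0,
    sigma_tech: float = 0.0,
    efficiencies: dict[str, float] | None = None,
    intercept: float = 20.0,
    max_ct: float = 35.0,
    n_tech: int = 3,
    housekeeping: str = "myosin",
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a qRT-PCR Ct table under exponential amplification.

    ``concentrations[gene][group]`` is the true relative transcript
    concentration; Ct = intercept - log_E(concentration) + biological
    effect N(0, sigma_bio) + technical noise N(0, sigma_tech).  Readings
    above ``max_ct`` are emitted censored (empty Ct).  The housekeeping
    gene is added at concentration 1 in every group unless planned
    explicitly.  Pure function of (parameters, seed).
    """
    if sigma_bio < 0 or sigma_tech < 0:
        raise ParameterError("noise standard deviations must be >= 0")
    for gene, per_group in concentrations.items():
        for grp, conc in per_group.items():
            if not conc > 0:
                raise ParameterError(f"{gene}/{grp}: concentration must be positive")
    eff = dict(efficiencies or {})
    genes = sorted(concentrations)
    if housekeeping not in concentrations:
        genes = genes + [housekeeping]
    conc_of = dict(concentrations)
    conc_of.setdefault(housekeeping, {g.name: 1.0 for g in groups})

    rng = np.random.default_rng(seed)
    rows = []
    for grp in groups:
        for gene in genes:
            e = eff.get(gene, 2.0)
            conc = conc_of[gene].get(grp.name)
            if conc is None:
                continue
            base = intercept - math.log(conc) / math.log(e)
            for b in range(1, grp.n_bio + 1):
                bio = rng.normal(0.0, sigma_bio) if sigma_bio > 0 else 0.0
                for t in range(1, n_tech + 1):
                    tech = rng.normal(0.0, sigma_tech) if sigma_tech > 0 else 0.0
                    ct = base + bio + tech
                    rows.append(
                        {
                            "gene": gene,
                            "sample_id": f"{grp.name}|b{b}",
                            "root_type": grp.root_type,
                            "stage": grp.stage,
                            "treatment_time": grp.treatment_time,
                            "bio_rep": b,
                            "tech_rep": t,
                            "ct": round(ct, 6) if ct <= max_ct else np.nan,
                        }
                    )
    table = pd.DataFrame(rows)
    truth = SimulationTruth(
        rng_seed=seed,
        concentrations={g: dict(v) for g, v in conc_of.items()},
        efficiencies={g: eff.get(g, 2.0) for g in genes},
        metadata={
            "sigma_bio": sigma_bio, "sigma_tech": sigma_tech,
            "intercept": intercept, "max_ct": max_ct,
            "housekeeping": housekeeping, "treatment": TREATMENT_METADATA,
        },
    )
    return table, truth


def root_type_design(
    n_genes: int = 30,
    *,
    fold_step: float = 2.0,
    base_concentration: float = 1.0,
    order: tuple[str, ...] = ("crown", "seminal", "primary", "lateral"),
    n_bio: int = 5,
    seed: int = 0,
) -> tuple[list[GroupSpec], dict[str, dict[str, float]]]:
    """Design with group means following the planted root-type
    hierarchy: each step down the order divides the concentration by
    ``fold_step``.  Per-gene baselines are log-uniform over two decades.
    """
    rng = np.random.default_rng(seed)
    groups = [GroupSpec(name=rt, root_type=rt, n_bio=n_bio) for rt in order]
    conc: dict[str, dict[str, float]] = {}
    for i in range(n_genes):
        gene = f"SynIAA{i + 1:02d}"
        base = base_concentration * 10 ** rng.uniform(-1, 1)
        conc[gene] = {rt: base / fold_step**k for k, rt in enumerate(order)}
    return groups, conc


# ---------------------------------------------------------------------------
# induction time courses

_PATTERN_MEANS = {
    "A": lambda e: (1.0, e, e, e),
    "B": lambda e: (1.0, e, 1.0, 1.0),
    "flat": lambda e: (1.0, 1.0, 1.0, 1.0),
}


def simulate_induction_course(
    label: str,
    effect_size: float = 3.0,
    cv: float = 0.2,
    *,
    gene: str = "gene",
    n_reps: int = 3,
    seed: int = 0,
) -> InductionSeries:
    """One auxin-induction time course with a planted kinetics label.

    Mean trajectories over (t0, t1, t2, t3): sustained rise for ``A``,
    rise-then-return for ``B``, constant for ``flat``; replicates are
    log-normal around the means with coefficient of variation ``cv``.
    """
    if label not in _PATTERN_MEANS:
        raise ParameterError(f"unknown induction label {label!r} (A, B or flat)")
    if effect_size < 1:
        raise ParameterError("effect_size must be >= 1")
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    means = _PATTERN_MEANS[label](effect_size)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv**2))
    values = {}
    for t, mu in zip(TIME_POINTS, means):
        if cv > 0:
            # log-normal with mean mu and CV cv
            values[t] = mu * np.exp(rng.normal(-sigma**2 / 2, sigma, size=n_reps))
        else:
            values[t] = np.full(n_reps, mu)
    return InductionSeries(gene=gene, values=values)


def simulate_induction_batch(
    labels: dict[str, str],
    effect_size: float = 3.0,
    cv: float = 0.2,
    *,
    n_reps: int = 3,
    seed: int = 0,
) -> tuple[list[InductionSeries], SimulationTruth]:
    """Planted time courses for many genes (one child seed per gene)."""
    root = np.random.default_rng(seed)
    child = {g: int(s) for g, s in zip(sorted(labels), root.integers(0, 2**31 - 1, len(labels)))}
    series = [
        simulate_induction_course(
            labels[g], effect_size, cv, gene=g, n_reps=n_reps, seed=child[g]
        )
        for g in sorted(labels)
    ]
    truth = SimulationTruth(
        rng_seed=seed,
        induction_labels=dict(labels),
        induction_effects={g: effect_size for g in labels},
        metadata={"cv": cv, "n_reps": n_reps, "treatment": TREATMENT_METADATA},
    )
    return series, truth


# ---------------------------------------------------------------------------
# dilution series

def simulate_dilution_series(
    efficiency: float = 2.0,
    *,
    intercept: float = 20.0,
    sigma: float = 0.0,
    dilutions=DILUTION_SERIES,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard-curve Ct readings for a primer of known efficiency."""
    if not 1.0 < efficiency <= 2.2:
        raise ParameterError("efficiency must be in (1, 2.2]")
    d = np.asarray(dilutions, dtype=float)
    rng = np.random.default_rng(seed)
    cts = intercept - np.log(d) / math.log(efficiency)
    if sigma > 0:
        cts = cts + rng.normal(0.0, sigma, size=len(d))
    return d, cts


# ---------------------------------------------------------------------------
# family sequences

def default_family_plan(n_genes: int = 34) -> list[GenePlan]:
    """Architecture plan mirroring the family's published composition
    (29 canonical of 34; defective, variant-motif and class-B subsets;
    seven duplicate pairs; 28 promoters with a canonical AuxRE)."""
    partner = {}
    for a, b in DEFAULT_PARALOG_PAIRS:
        if a <= n_genes and b <= n_genes:
            partner[a], partner[b] = b, a
    plans = []
    for i in range(1, n_genes + 1):
        name = f"SynIAA{i:02d}"
        domains: tuple[str, ...] = ("I", "II", "III", "IV")
        incomplete: tuple[str, ...] = ()
        if i in DEFAULT_NO_D1_D2:
            domains = ("III", "IV")
            incomplete = ("III", "IV")
        elif i in DEFAULT_NO_D2:
            domains = ("I", "III", "IV")
        elif i in DEFAULT_NO_D4:
            domains = ("I", "II", "III")
        has_d1 = "I" in domains
        has_d2 = "II" in domains
        has_d4 = "IV" in domains and "IV" not in incomplete
        plans.append(
            GenePlan(
                name=name,
                domains=domains,
                incomplete=incomplete,
                split_iv=i in DEFAULT_SPLIT_D4,
                repressor=("LxLxPP" if i in DEFAULT_LXLXPP else "LxLxLP") if has_d1 else "absent",
                degron=has_d2,
                nls_bipartite=has_d1 and has_d2,
                nls_cterminal=has_d4,
                family_class="B" if i in DEFAULT_CLASS_B else "A",
                n_canonical_auxre=0 if i in DEFAULT_NO_CANONICAL_AUXRE else 1 + (i % 3),
                n_core_tandem=3,
                paralog_partner=f"SynIAA{partner[i]:02d}" if i in partner else None,
            )
        )
    return plans


def _random_linker(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _aligned_row(plan: GenePlan, rng: np.random.Generator) -> str:
    """One protein as a fixed-layout aligned row ('-' = absent column)."""
    l0, l1, l2, l3, l4 = (_random_linker(rng, n) for n in LINKER_LENS)
    if plan.nls_bipartite:
        l1 = l1[:3] + "KR" + l1[5:]

    d1 = D1_FLANKS[0] + REPRESSOR_SLOT[plan.repressor] + D1_FLANKS[1]
    d2 = D2_FLANKS[0] + DEGRON_SLOT[plan.degron] + D2_FLANKS[1] + \
        HEXAMER_SLOT[plan.nls_bipartite] + D2_FLANKS[2]
    sig = CLASS_SIGNATURE[plan.family_class]
    d3 = D3_FLANKS[0] + sig + D3_FLANKS[1]
    core7 = _random_linker(rng, 7)
    d4a = D4_FLANKS[0] + core7[:4]
    d4b = core7[4:] + CTERM_NLS_SLOT[plan.nls_cterminal] + D4_FLANKS[1]
    insertion = _random_linker(rng, SPLIT_INSERTION_LEN) if plan.split_iv \
        else "-" * SPLIT_INSERTION_LEN

    if "I" not in plan.domains:
        d1 = "-" * len(d1)
    if "II" not in plan.domains:
        d2 = "-" * len(d2)
    if "III" not in plan.domains:
        d3 = "-" * len(d3)
    elif "III" in plan.incomplete:
        partial = D3_FLANKS[0] + sig[:4]
        d3 = partial + "-" * (len(d3) - len(partial))
    if "IV" not in plan.domains:
        d4a = "-" * len(d4a)
        d4b = "-" * len(d4b)
    elif "IV" in plan.incomplete:
        d4b = "-" * len(d4b)

    return l0 + d1 + l1 + d2 + l2 + d3 + l3 + d4a + insertion + d4b + l4


def _count(pattern: str, seq: str) -> int:
    return len(re.findall(f"(?:(?={pattern}))", seq))


def _sequence_ok(row: str, plan: GenePlan) -> bool:
    """Reject assemblies whose random filler re-creates a planted motif
    or pattern anchor, so presence/absence truth stays exact."""
    from .config import DEFAULT_DOMAIN_PROFILES  # local import avoids a cycle

    seq = row.replace("-", "")
    for dom, prof in DEFAULT_DOMAIN_PROFILES.items():
        present = dom in plan.domains
        full_expected = int(present and dom not in plan.incomplete
                            and not (dom == "IV" and plan.split_iv))
        if _count(prof.full, seq) != full_expected:
            return False
        if prof.partial is not None:
            # the truncated remnant must exist exactly when planted; the
            # full domain also contains its own prefix remnant
            partial_expected = int(present)
            if _count(prof.partial, seq) != partial_expected:
                return False
    # flank anchors must be unique so spans are unambiguous
    for anchor, present in (("TE", "I" in plan.domains), ("GSEE", "I" in plan.domains),
                            ("KAQ", "II" in plan.domains), ("GFS", "III" in plan.domains),
                            ("PWN", "IV" in plan.domains),
                            ("EM", "IV" in plan.domains and "IV" not in plan.incomplete)):
        if _count(anchor, seq) != int(present):
            return False
    if _count(DEGRON_SLOT[True], seq) != int(plan.degron):
        return False
    # "KR" only in the planted bipartite linker + hexamer (and the
    # C-terminal NLS block KKRK contributes one more)
    kr_expected = (
        _count("KR", "KR" + HEXAMER_SLOT[True]) * int(plan.nls_bipartite)
        + _count("KR", CTERM_NLS_SLOT[True]) * int(plan.nls_cterminal)
    )
    if _count("KR", seq) != kr_expected:
        return False
    # basic four-residue stretches only where planted
    basic4_expected = (
        _count(r"[KR]{4}", HEXAMER_SLOT[True]) * int(plan.nls_bipartite)
        + _count(r"[KR]{4}", CTERM_NLS_SLOT[True]) * int(plan.nls_cterminal)
    )
    if _count(r"[KR]{4}", seq) != basic4_expected:
        return False
    return True


def _mutate_linkers(row: str, rng: np.random.Generator, rate: float = 0.08) -> str:
    """Point substitutions confined to linker columns (keeps all planted
    domain content intact) -- used to diverge duplicate pairs."""
    cum = 0
    linker_cols = []
    d1_len = len(D1_FLANKS[0]) + 6 + len(D1_FLANKS[1])
    d2_len = len(D2_FLANKS[0]) + 5 + len(D2_FLANKS[1]) + 6 + len(D2_FLANKS[2])
    d3_len = len(D3_FLANKS[0]) + 8 + len(D3_FLANKS[1])
    d4a_len = len(D4_FLANKS[0]) + 4
    d4b_len = 3 + 4 + len(D4_FLANKS[1])
    blocks = [
        (LINKER_LENS[0], True), (d1_len, False), (LINKER_LENS[1], False),
        (d2_len, False), (LINKER_LENS[2], True), (d3_len, False),
        (LINKER_LENS[3], True), (d4a_len, False), (SPLIT_INSERTION_LEN, False),
        (d4b_len, False), (LINKER_LENS[4], True),
    ]
    for size, is_linker in blocks:
        if is_linker:
            linker_cols.extend(range(cum, cum + size))
        cum += size
    chars = list(row)
    for col in linker_cols:
        if chars[col] != "-" and rng.random() < rate:
            chars[col] = rng.choice(list(AA))
    return "".join(chars)


def _motif_free_filler(rng: np.random.Generator, length: int, max_rounds: int = 200) -> str:
    """Random nucleotide filler repaired until free of AuxRE cores."""
    seq = list(rng.choice(list(NT), size=length))
    for _ in range(max_rounds):
        s = "".join(seq)
        hit = min((s.find(m) for m in AUXRE_CORES if s.find(m) != -1), default=-1)
        if hit == -1:
            return s
        for k in range(4):
            seq[hit + k] = "A"
    raise ParameterError("could not build motif-free filler")  # pragma: no cover


def _build_promoter(
    plan: GenePlan, length: int, rng: np.random.Generator, tandem_gap: int = 8
) -> tuple[str, dict[str, int]]:
    """Promoter with ``n_canonical_auxre`` isolated canonical elements
    and one tandem run of ``n_core_tandem`` core motifs."""
    filler = _motif_free_filler(rng, length)
    seq = list(filler)
    positions = []
    spacing = 150
    for i in range(plan.n_canonical_auxre):
        pos = 100 + spacing * i
        seq[pos : pos + len(AUXRE_CANONICAL)] = AUXRE_CANONICAL
        positions.append(pos)
    # keep the tandem run >50 bp clear of the last canonical element so
    # the planted cluster stays exactly the tandem copies
    last_canon = positions[-1] + len(AUXRE_CANONICAL) if positions else 0
    tandem_start = max(length - 150, last_canon + 100)
    for i in range(plan.n_core_tandem):
        pos = tandem_start + i * tandem_gap
        seq[pos : pos + 4] = "TGTC"
        if i + 1 < plan.n_core_tandem:
            # A-fill between copies: filler there could otherwise extend
            # a core into a spurious canonical element (TGTC + TC)
            seq[pos + 4 : tandem_start + (i + 1) * tandem_gap] = \
                "A" * (tandem_gap - 4)
        else:
            seq[pos + 4 : pos + 6] = "AA"
    out = "".join(seq)
    counts = {
        "canonical": plan.n_canonical_auxre,
        "core_tandem": plan.n_core_tandem,
        "tandem_start": tandem_start,
    }
    return out, counts


def simulate_family_sequences(
    n_genes: int = 34,
    plans: list[GenePlan] | None = None,
    *,
    promoter_length: int = 3000,
    divergence: float = 0.08,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[tuple[str, str]], SimulationTruth]:
    """Generate proteins, promoters and a protein alignment with
    planted architectures, motifs, AuxRE content and duplicate pairs.

    Duplicate pairs are created by copying one member's assembled row
    and substituting linker columns at rate ``divergence``; unrelated
    genes get independent random linkers, so the pairs stand out as
    tightly supported cherries in the reconstructed tree.

    Returns ``(proteins, promoters, alignment, truth)``; the alignment
    is the fixed column layout with '-' for absent blocks.
    """
    if plans is None:
        plans = default_family_plan(n_genes)
    if len(plans) < 2:
        raise ParameterError("need at least 2 genes")
    by_name = {p.name: p for p in plans}
    rng = np.random.default_rng(seed)

    if promoter_length < 600:
        raise ParameterError("promoter_length must be >= 600 for the planted layout")

    rows: dict[str, str] = {}
    for plan in plans:
        if plan.paralog_partner and plan.paralog_partner in rows:
            base = rows[plan.paralog_partner]
            partner_plan = by_name[plan.paralog_partner]
            if (plan.domains, plan.incomplete) != (partner_plan.domains, partner_plan.incomplete):
                raise ParameterError(
                    f"{plan.name}: paralog partners must share a domain layout"
                )
            for _ in range(100):
                row = _mutate_linkers(base, rng, rate=divergence)
                if plan.split_iv != partner_plan.split_iv:
                    # partners may differ in the split-IV insertion
                    ins = _random_linker(rng, SPLIT_INSERTION_LEN) if plan.split_iv \
                        else "-" * SPLIT_INSERTION_LEN
                    a = _INSERTION_COL
                    row = row[:a] + ins + row[a + SPLIT_INSERTION_LEN:]
                if _sequence_ok(row, plan):
                    break
            else:  # pragma: no cover
                raise ParameterError(f"{plan.name}: could not diverge paralog cleanly")
        else:
            for _ in range(100):
                row = _aligned_row(plan, rng)
                if _sequence_ok(row, plan):
                    break
            else:  # pragma: no cover
                raise ParameterError(f"{plan.name}: could not assemble clean sequence")
        rows[plan.name] = row

    alignment = [(p.name, rows[p.name]) for p in plans]
    proteins = [(p.name, rows[p.name].replace("-", "")) for p in plans]

    promoters = []
    promoter_counts = {}
    for plan in plans:
        seq, counts = _build_promoter(plan, promoter_length, rng)
        promoters.append((plan.name, seq))
        promoter_counts[plan.name] = counts

    pairs = sorted(
        tuple(sorted((p.name, p.paralog_partner)))
        for p in plans if p.paralog_partner is not None
    )
    truth = SimulationTruth(
        rng_seed=seed,
        gene_plans={p.name: dataclasses.asdict(p) for p in plans},
        paralog_pairs=sorted(set(pairs)),
        promoter_counts=promoter_counts,
        metadata={"promoter_length": promoter_length, "divergence": divergence},
    )
    log.info(
        "simulated family: %d genes, %d canonical, %d duplicate pairs",
        len(plans), sum(p.canonical for p in plans), len(set(pairs)),
    )
    return proteins, promoters, alignment, truth
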