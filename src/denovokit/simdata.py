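"""Synthetic multi-child family cohorts with germline de novo SNVs.

Everything downstream of read alignment is emulated here at summary level: a
toy genome with CpG islands, pedigrees with paternal ages, Poisson DNM counts
rising with paternal age, trinucleotide contexts drawn from a signature
mixture and placed at matching genome positions, two pseudo-caller discovery
call sets carrying trio read metrics plus three artifact classes (parental
mosaics, sequencing noise, cross-child recurrent sites), deep-resequencing
validation readouts, phase-informative read fragments, and random reference
signature catalogs (96-channel and strand-resolved 192-channel).

The generator defines "truth" as *recoverable* de novo SNVs: read evidence
for true variants is drawn conditionally on clearing the discovery and
validation thresholds (the rejected mass is <0.5%), so a no-artifact run
validates exactly the truth set.  Cohort-wide site placement is sampled
without replacement, so true DNMs never recur across children and are never
swept up by the recurrence filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sigkit import CHANNELS_96, CPG_CHANNELS

__all__ = [
    "SimConfig",
    "Cohort",
    "simulate_genome",
    "write_fasta",
    "read_fasta",
    "build_context_index",
    "default_signature_catalog",
    "simulate_cohort",
    "simulate_discovery_calls",
    "simulate_validation_readouts",
    "simulate_fragments",
    "make_reference_catalogs",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

CANDIDATE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "child_id", "family_id", "callers",
    "child_depth", "child_alt", "child_alt_fwd", "child_alt_rev",
    "father_depth", "father_alt", "mother_depth", "mother_alt",
    "child_gq", "father_gq", "mother_gq",
]


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    Defaults reproduce the study conditions of a 13-family, ~48-proband
    multi-sibling cohort: ~52 validated SNVs per proband at a mean paternal
    age of ~27.5 y, a pooled paternal-age slope of 1.29 SNVs/y with
    substantial between-family spread, 78.6% paternal origin, ~30X discovery
    and ~300X validation depth, and enough artifact load to land discovery
    candidates near ~235 per child.
    """

    n_families: int = 13
    children_range: tuple[int, int] = (2, 6)
    children_dist: tuple[float, float] = (3.7, 1.2)  # mean, sd; rounded + clipped to range
    age_at_first_child_dist: tuple[float, float] = (23.0, 4.0)  # mean, sd (years)
    interbirth_gap_dist: tuple[float, float] = (3.4, 1.5)  # mean, sd (years)
    alpha: float = 16.1  # expected SNVs at paternal age 0
    beta_mean: float = 1.29  # SNVs per year of paternal age
    beta_sd: float = 2.4  # between-family slope spread (range estimator over the 13 observed slopes)
    p_paternal: float = 0.786
    signature_weights: dict = field(
        default_factory=lambda: {"SBSclock": 0.85, "SBSdeam": 0.15}
    )
    cpg_signature: str = "SBSdeam"
    cpg_age_shift: float = 0.008  # weight shift toward the CpG signature per year
    age_ref: float = 27.5  # pivot age for the CpG weight shift
    discovery_depth_mean: float = 30.0
    validation_depth_mean: float = 300.0
    artifact_rates: dict = field(
        default_factory=lambda: {"parental_mosaic": 20.0, "seq_noise": 150.0, "recurrent": 12.5}
    )
    callerb_recall: float = 0.22  # fraction of caller-A records also emitted by B
    callerb_private_rate: float = 4.0  # B-private artifacts per child
    bait_success_rate: float = 1.0  # fraction of candidates with a designed bait
    phaseable_fraction: float = 0.104  # DNMs with informative linked fragments
    genome_length: int = 1_000_000
    gc_content: float = 0.41
    cpg_island_fraction: float = 0.02
    callable_diploid_bp: float = 5.0e9  # mutation-rate denominator (reported, not derived)
    seed: int = 0

    def validate(self) -> "SimConfig":
        errs = []
        if self.children_range[0] < 2 or self.children_range[0] > self.children_range[1]:
            errs.append("children_range low must be >= 2 and <= high")
        if not 0.0 <= self.p_paternal <= 1.0:
            errs.append("p_paternal must lie in [0, 1]")
        if abs(sum(self.signature_weights.values()) - 1.0) > 1e-9:
            errs.append("signature_weights must sum to 1")
        for k, v in self.artifact_rates.items():
            if v < 0:
                errs.append(f"artifact rate {k} must be >= 0")
        for name, v in [
            ("alpha", self.alpha), ("discovery_depth_mean", self.discovery_depth_mean),
            ("validation_depth_mean", self.validation_depth_mean),
            ("bait_success_rate", self.bait_success_rate),
            ("phaseable_fraction", self.phaseable_fraction),
        ]:
            if v < 0:
                errs.append(f"{name} must be >= 0")
        if errs:
            raise ValueError("invalid SimConfig: " + "; ".join(errs))
        return self

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream for a pipeline stage."""
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class Cohort:
    """A simulated cohort plus its accumulated truth and call tables."""

    config: SimConfig
    pedigrees: pd.DataFrame  # family_id, father_id, mother_id, child_id, birth_order, paternal_age
    truth: pd.DataFrame  # one row per true DNM
    expected: pd.DataFrame  # per-child generating slope and Poisson mean
    artifacts: pd.DataFrame | None = None
    candidates: pd.DataFrame | None = None
    readouts: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    length: int,
    gc: float = 0.41,
    cpg_frac: float = 0.02,
    seed: int = 0,
    chrom: str = "chr1",
    island_length: int = 200,
) -> dict[str, str]:
    """Random toy genome with optional CpG islands.

    Base composition follows ``gc``; a fraction ``cpg_frac`` of the sequence
    is covered by islands where CpG dinucleotides are planted far above the
    background expectation.  Deterministic for a fixed seed.
    """
    if length < 10_000:
        raise ValueError(f"genome length {length} below the 10 kb minimum")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=length, p=p).astype(np.int8)
    if cpg_frac > 0:
        n_islands = max(1, int(round(length * cpg_frac / island_length)))
        starts = rng.choice(length - island_length, size=n_islands, replace=False)
        for s in starts:
            # plant CG pairs on ~15% of island positions
            offs = np.flatnonzero(rng.random(island_length - 1) < 0.075)
            arr[s + offs] = 1  # C
            arr[s + offs + 1] = 2  # G
    seq = _BASES[arr].tobytes().decode("ascii")
    return {chrom: seq}


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA (via pyfaidx) into plain chrom -> sequence strings."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


class ContextIndex:
    """Positions of every pyrimidine-strand trinucleotide context in a genome."""

    def __init__(self, genome: dict[str, str]):
        self.genome = genome
        self.positions: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            enc = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            code = np.full(len(enc), 255, dtype=np.uint8)
            for i, b in enumerate(b"ACGT"):
                code[enc == b] = i
            a, b, c = code[:-2], code[1:-1], code[2:]
            valid = (a < 4) & (b < 4) & (c < 4)
            pyr = (b == 1) | (b == 3)
            fwd = a * 16 + b * 4 + c
            rev = (3 - c) * 16 + (3 - b) * 4 + (3 - a)
            ctx = np.where(pyr, fwd, rev)
            pos1 = np.arange(2, len(enc), dtype=np.int64)  # 1-based centre positions
            for key_code in np.unique(ctx[valid]):
                tri = "".join("ACGT"[d] for d in (key_code // 16, (key_code // 4) % 4, key_code % 4))
                sel = pos1[valid & (ctx == key_code)]
                self.positions.setdefault(tri, []).extend((chrom, int(p)) for p in sel)

    def n_positions(self, context: str) -> int:
        return len(self.positions.get(context, []))


def build_context_index(genome: dict[str, str]) -> ContextIndex:
    return ContextIndex(genome)


# ---------------------------------------------------------------------------
# signatures


def default_signature_catalog() -> pd.DataFrame:
    """Two built-in generating signatures.

    ``SBSdeam`` concentrates on C>T at CpG motifs (spontaneous deamination of
    5-methylcytosine); ``SBSclock`` is a broad clock-like background leaning
    on T>C and non-CpG C>T, mimicking the flat age-correlated signature that
    dominates germline SNVs.
    """
    deam = pd.Series(0.0, index=list(CHANNELS_96))
    for ch in CPG_CHANNELS:
        deam[ch] = 0.17
    other_ct = [c for c in CHANNELS_96 if "[C>T]" in c and c not in CPG_CHANNELS]
    for ch in other_ct:
        deam[ch] = 0.32 / len(other_ct)
    deam /= deam.sum()

    clock = pd.Series(0.40 / 68, index=list(CHANNELS_96))
    tc = [c for c in CHANNELS_96 if "[T>C]" in c]
    for ch in tc:
        clock[ch] = 0.35 / len(tc)
    for ch in other_ct:
        clock[ch] = 0.25 / len(other_ct)
    for ch in CPG_CHANNELS:
        clock[ch] = 0.40 / 68
    clock /= clock.sum()

    cat = pd.DataFrame({"SBSclock": clock, "SBSdeam": deam})
    cat.index.name = "Type"
    return cat


def _mixture_for_age(config: SimConfig, catalog: pd.DataFrame, age: float) -> np.ndarray:
    """96-channel probability vector at a given paternal age."""
    w = dict(config.signature_weights)
    cpg = config.cpg_signature
    if config.cpg_age_shift and cpg in w:
        target = float(np.clip(w[cpg] + config.cpg_age_shift * (age - config.age_ref), 0.01, 0.95))
        others = {k: v for k, v in w.items() if k != cpg}
        tot = sum(others.values())
        w = {k: v * (1 - target) / tot for k, v in others.items()}
        w[cpg] = target
    vec = np.zeros(96)
    for name, weight in w.items():
        vec += weight * catalog[name].to_numpy()
    return vec / vec.sum()


# ---------------------------------------------------------------------------
# cohort


def _simulate_pedigrees(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    lo, hi = config.children_range
    m1, s1 = config.age_at_first_child_dist
    mg, sg = config.interbirth_gap_dist
    mc, sc = config.children_dist
    for f in range(1, config.n_families + 1):
        fam = f"F{f:02d}"
        n_ch = int(np.clip(round(rng.normal(mc, sc)), lo, hi))
        age = max(16.0, rng.normal(m1, s1))
        for i in range(1, n_ch + 1):
            rows.append(
                {
                    "family_id": fam,
                    "father_id": f"{fam}-father",
                    "mother_id": f"{fam}-mother",
                    "child_id": f"{fam}-p{i}",
                    "birth_order": i,
                    "paternal_age": round(age, 1),
                }
            )
            age += max(0.6, rng.normal(mg, sg))
    return pd.DataFrame(rows)


def simulate_cohort(
    config: SimConfig,
    genome: dict[str, str] | None = None,
    context_index: ContextIndex | None = None,
    catalog: pd.DataFrame | None = None,
    sites: bool = True,
    max_channel_retries: int = 50,
) -> Cohort:
    """Draw pedigrees and true DNMs under the paternal-age-effect model.

    Per family the slope beta_f ~ Normal(beta_mean, beta_sd); per child the
    DNM count is Poisson with mean

        max(alpha + beta_mean * age + (beta_f - beta_mean) * (age - agebar_f), 0.1)

    where agebar_f is the family's mean paternal age: family slopes pivot at
    the family's own age centre, so slope heterogeneity spreads the trend
    without inflating count levels (families with negative slopes still carry
    cohort-typical counts, as observed in real multi-sibling data).  With
    beta_sd = 0 this reduces to the plain linear mean alpha + beta * age.
    Parent of origin is Bernoulli(p_paternal).  Each DNM's 96-channel is drawn from the
    signature mixture (CpG weight optionally drifting with age) and, when a
    genome is supplied and ``sites`` is true, placed at a genome position
    whose pyrimidine-strand context matches — sampled without replacement
    cohort-wide so no true site recurs.
    """
    config.validate()
    rng = config.rng(1)
    if catalog is None:
        catalog = default_signature_catalog()
    for name in config.signature_weights:
        if name not in catalog.columns:
            raise ValueError(f"signature_weights references unknown signature {name!r}")

    ped = _simulate_pedigrees(config, rng)

    exp_rows = []
    truth_parts = []
    channel_arr = np.array(CHANNELS_96)
    betas = {fam: rng.normal(config.beta_mean, config.beta_sd) for fam in ped["family_id"].unique()}
    agebar = ped.groupby("family_id")["paternal_age"].mean()
    for r in ped.itertuples(index=False):
        beta_f = betas[r.family_id]
        lam = max(
            config.alpha
            + config.beta_mean * r.paternal_age
            + (beta_f - config.beta_mean) * (r.paternal_age - agebar[r.family_id]),
            0.1,
        )
        n = int(rng.poisson(lam))
        exp_rows.append(
            {
                "family_id": r.family_id,
                "child_id": r.child_id,
                "paternal_age": r.paternal_age,
                "beta_family": beta_f,
                "expected_count": lam,
                "n_true": n,
            }
        )
        if n == 0:
            continue
        mix = _mixture_for_age(config, catalog, r.paternal_age)
        chan_idx = rng.choice(96, size=n, p=mix)
        paternal = rng.random(n) < config.p_paternal
        truth_parts.append(
            pd.DataFrame(
                {
                    "family_id": r.family_id,
                    "child_id": r.child_id,
                    "paternal_age": r.paternal_age,
                    "channel": channel_arr[chan_idx],
                    "parent_of_origin": np.where(paternal, "paternal", "maternal"),
                }
            )
        )
    expected = pd.DataFrame(exp_rows)
    if truth_parts:
        truth = pd.concat(truth_parts, ignore_index=True)
    else:
        truth = pd.DataFrame(
            columns=["family_id", "child_id", "paternal_age", "channel", "parent_of_origin"]
        )

    if sites and genome is not None and len(truth):
        if context_index is None:
            context_index = build_context_index(genome)
        truth = _place_contexts(truth, context_index, rng, max_channel_retries)
    else:
        truth["chrom"] = pd.NA
        truth["pos"] = pd.NA
        truth["ref"] = pd.NA
        truth["alt"] = pd.NA

    truth["record_class"] = "dnm"
    cols = [
        "family_id", "child_id", "chrom", "pos", "ref", "alt",
        "channel", "parent_of_origin", "paternal_age", "record_class",
    ]
    truth = truth[cols]
    return Cohort(config=config, pedigrees=ped, truth=truth, expected=expected)


def _place_contexts(
    truth: pd.DataFrame,
    index: ContextIndex,
    rng: np.random.Generator,
    max_retries: int,
) -> pd.DataFrame:
    """Assign genome sites matching each DNM's channel, unique cohort-wide."""
    import warnings as _w

    truth = truth.copy()
    ctx = truth["channel"].str.replace(r"\[(\w)>(\w)\]", lambda m: m.group(1), regex=True)
    truth["_context"] = ctx
    chrom = np.empty(len(truth), dtype=object)
    pos = np.zeros(len(truth), dtype=np.int64)
    ref = np.empty(len(truth), dtype=object)
    alt = np.empty(len(truth), dtype=object)
    for context, grp in truth.groupby("_context"):
        avail = index.positions.get(context, [])
        need = len(grp)
        if not avail:
            raise ValueError(f"toy genome has no site with context {context}; enlarge it")
        if len(avail) < need:
            _w.warn(
                f"context {context} has only {len(avail)} genome sites for {need} DNMs; "
                "sampling with replacement",
                stacklevel=2,
            )
            pick = rng.integers(0, len(avail), size=need)
        else:
            pick = rng.choice(len(avail), size=need, replace=False)
        for row_i, p_i in zip(grp.index, pick):
            c, p = avail[p_i]
            chrom[row_i] = c
            pos[row_i] = p
    truth["chrom"] = chrom
    truth["pos"] = pos
    # derive strand-correct ref/alt from the genome base
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    refs, alts = [], []
    for r in truth.itertuples(index=False):
        base = index.genome[r.chrom][r.pos - 1]
        chan_ref, chan_alt = r.channel[2], r.channel[4]
        if base == chan_ref:
            refs.append(base)
            alts.append(chan_alt)
        else:
            refs.append(base)
            alts.append(comp[chan_alt])
    truth["ref"] = refs
    truth["alt"] = alts
    return truth.drop(columns="_context")


# ---------------------------------------------------------------------------
# discovery calls


def _gq(depth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Saturating GQ-vs-depth curve with additive noise."""
    base = 99.0 * (1.0 - np.exp(-np.asarray(depth, dtype=float) / 12.0))
    return np.clip(np.round(base + rng.normal(0, 3, size=len(base))), 0, 99).astype(int)


def _true_evidence(n: int, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Trio discovery metrics for true DNMs, conditioned on clearing the filters."""
    out = {}
    dp = config.discovery_depth_mean

    def cond_poisson(minimum):
        x = rng.poisson(dp, size=n)
        bad = x < minimum
        while bad.any():
            x[bad] = rng.poisson(dp, size=int(bad.sum()))
            bad = x < minimum
        return x

    child_depth = cond_poisson(12)
    father_depth = cond_poisson(12)
    mother_depth = cond_poisson(12)
    alt = rng.binomial(child_depth, 0.5)
    fwd = rng.binomial(alt, 0.5)
    bad = (fwd < 2) | (alt - fwd < 2)
    while bad.any():
        k = int(bad.sum())
        alt[bad] = rng.binomial(child_depth[bad], 0.5)
        fwd[bad] = rng.binomial(alt[bad], 0.5)
        bad = (fwd < 2) | (alt - fwd < 2)

    def cond_gq(depth):
        g = _gq(depth, rng)
        bad = g < 20
        while bad.any():
            g[bad] = _gq(depth[bad], rng)
            bad = g < 20
        return g

    out["child_depth"] = child_depth
    out["child_alt"] = alt
    out["child_alt_fwd"] = fwd
    out["child_alt_rev"] = alt - fwd
    out["father_depth"] = father_depth
    out["father_alt"] = np.zeros(n, dtype=int)
    out["mother_depth"] = mother_depth
    out["mother_alt"] = np.zeros(n, dtype=int)
    out["child_gq"] = cond_gq(child_depth)
    out["father_gq"] = cond_gq(father_depth)
    out["mother_gq"] = cond_gq(mother_depth)
    return pd.DataFrame(out)


def _random_sites(
    n: int,
    genome: dict[str, str],
    rng: np.random.Generator,
    used: set,
) -> tuple[list[str], list[int], list[str], list[str]]:
    """Random interior genome sites (with a random alt) avoiding ``used`` keys."""
    comp_pool = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    chroms = list(genome)
    cs, ps, rs, as_ = [], [], [], []
    while len(cs) < n:
        chrom = chroms[int(rng.integers(len(chroms)))]
        seq = genome[chrom]
        pos = int(rng.integers(2, len(seq)))
        ref = seq[pos - 1]
        if ref not in "ACGT":
            continue
        alt = comp_pool[ref][int(rng.integers(3))]
        if (chrom, pos, alt) in used:
            continue
        used.add((chrom, pos, alt))
        cs.append(chrom)
        ps.append(pos)
        rs.append(ref)
        as_.append(alt)
    return cs, ps, rs, as_


def simulate_discovery_calls(
    cohort: Cohort,
    genome: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit pseudo-caller candidate tables from the truth plus artifacts.

    Caller A (DeNovoGear-like) emits every record; caller B (GATK-like) emits
    a configured subset of A plus a small private artifact set, so the B->A
    overlap sits above 90%.  Artifact classes: ``parental_mosaic`` (one parent
    carries the allele at a low fraction), ``seq_noise`` (low child allele
    fraction, strand-imbalanced), ``recurrent`` (the same site called in >=2
    children).  Returns (candidates, artifacts); the second table is the
    truth-side record of injected artifacts with their generating parameters.
    """
    config = cohort.config
    rng = config.rng(2)
    truth = cohort.truth
    if truth["pos"].isna().any():
        raise ValueError("truth table has no placed sites; simulate_cohort with a genome first")

    used = set(zip(truth["chrom"], truth["pos"].astype(int), truth["alt"]))
    children = cohort.pedigrees[["family_id", "child_id"]]

    parts = []
    true_part = truth[["chrom", "pos", "ref", "alt", "child_id", "family_id"]].copy()
    true_part = pd.concat([true_part.reset_index(drop=True), _true_evidence(len(truth), config, rng)], axis=1)
    true_part["record_class"] = "dnm"
    true_part["aux_frac"] = np.nan
    true_part["mosaic_parent"] = ""
    parts.append(true_part)

    rates = config.artifact_rates
    art_rows = []

    # parental mosaics: child evidence indistinguishable from a true DNM
    n_mos = rng.poisson(rates.get("parental_mosaic", 0.0), size=len(children))
    total = int(n_mos.sum())
    if total:
        cs, ps, rs, as_ = _random_sites(total, genome, rng, used)
        ev = _true_evidence(total, config, rng)
        fracs = rng.uniform(0.02, 0.25, size=total)
        which = np.where(rng.random(total) < 0.5, "father", "mother")
        child_ids = np.repeat(children["child_id"].to_numpy(), n_mos)
        fam_ids = np.repeat(children["family_id"].to_numpy(), n_mos)
        df = pd.DataFrame({"chrom": cs, "pos": ps, "ref": rs, "alt": as_, "child_id": child_ids, "family_id": fam_ids})
        df = pd.concat([df, ev], axis=1)
        for side in ("father", "mother"):
            sel = which == side
            df.loc[sel, f"{side}_alt"] = rng.binomial(df.loc[sel, f"{side}_depth"], fracs[sel])
        df["record_class"] = "parental_mosaic"
        df["aux_frac"] = fracs
        df["mosaic_parent"] = which
        parts.append(df)

    # sequencing noise: low AAF, strand-imbalanced
    n_noise = rng.poisson(rates.get("seq_noise", 0.0), size=len(children))
    total = int(n_noise.sum())
    if total:
        cs, ps, rs, as_ = _random_sites(total, genome, rng, used)
        depth = np.maximum(rng.poisson(config.discovery_depth_mean, size=total), 1)
        frac = rng.beta(2, 18, size=total)
        alt_n = np.maximum(rng.binomial(depth, frac), 1)
        fwd = rng.binomial(alt_n, 0.92)
        df = pd.DataFrame(
            {
                "chrom": cs, "pos": ps, "ref": rs, "alt": as_,
                "child_id": np.repeat(children["child_id"].to_numpy(), n_noise),
                "family_id": np.repeat(children["family_id"].to_numpy(), n_noise),
                "child_depth": depth, "child_alt": alt_n,
                "child_alt_fwd": fwd, "child_alt_rev": alt_n - fwd,
                "father_depth": rng.poisson(config.discovery_depth_mean, size=total),
                "father_alt": 0,
                "mother_depth": rng.poisson(config.discovery_depth_mean, size=total),
                "mother_alt": 0,
                "child_gq": _gq(depth, rng),
            }
        )
        df["father_gq"] = _gq(df["father_depth"].to_numpy(), rng)
        df["mother_gq"] = _gq(df["mother_depth"].to_numpy(), rng)
        df["record_class"] = "seq_noise"
        df["aux_frac"] = frac
        df["mosaic_parent"] = ""
        parts.append(df)

    # recurrent artifacts: same site called in >=2 children
    rec_rate = rates.get("recurrent", 0.0)
    if rec_rate > 0:
        target_occ = rec_rate * len(children)
        occ = 0
        rec_parts = []
        child_arr = children["child_id"].to_numpy()
        fam_by_child = dict(zip(children["child_id"], children["family_id"]))
        while occ < target_occ:
            k = 2 + int(rng.poisson(0.6))
            k = min(k, len(child_arr))
            cs, ps, rs, as_ = _random_sites(1, genome, rng, used)
            kids = rng.choice(child_arr, size=k, replace=False)
            ev = _true_evidence(k, config, rng)
            df = pd.DataFrame(
                {
                    "chrom": cs * k, "pos": ps * k, "ref": rs * k, "alt": as_ * k,
                    "child_id": kids,
                    "family_id": [fam_by_child[c] for c in kids],
                }
            )
            df = pd.concat([df, ev], axis=1)
            df["record_class"] = "recurrent"
            df["aux_frac"] = np.nan
            df["mosaic_parent"] = ""
            rec_parts.append(df)
            occ += k
        parts.extend(rec_parts)

    candidates = pd.concat(parts, ignore_index=True)

    # caller provenance: A emits everything; B a subset plus private noise
    in_b = rng.random(len(candidates)) < config.callerb_recall
    candidates["callers"] = np.where(in_b, "A,B", "A")

    n_priv = rng.poisson(config.callerb_private_rate, size=len(children))
    total = int(n_priv.sum())
    if total:
        cs, ps, rs, as_ = _random_sites(total, genome, rng, used)
        depth = np.maximum(rng.poisson(config.discovery_depth_mean, size=total), 1)
        frac = rng.beta(2, 18, size=total)
        alt_n = np.maximum(rng.binomial(depth, frac), 1)
        fwd = rng.binomial(alt_n, 0.92)
        df = pd.DataFrame(
            {
                "chrom": cs, "pos": ps, "ref": rs, "alt": as_,
                "child_id": np.repeat(children["child_id"].to_numpy(), n_priv),
                "family_id": np.repeat(children["family_id"].to_numpy(), n_priv),
                "child_depth": depth, "child_alt": alt_n,
                "child_alt_fwd": fwd, "child_alt_rev": alt_n - fwd,
                "father_depth": rng.poisson(config.discovery_depth_mean, size=total),
                "father_alt": 0,
                "mother_depth": rng.poisson(config.discovery_depth_mean, size=total),
                "mother_alt": 0,
                "child_gq": _gq(depth, rng),
            }
        )
        df["father_gq"] = _gq(df["father_depth"].to_numpy(), rng)
        df["mother_gq"] = _gq(df["mother_depth"].to_numpy(), rng)
        df["record_class"] = "seq_noise"
        df["aux_frac"] = frac
        df["mosaic_parent"] = ""
        df["callers"] = "B"
        candidates = pd.concat([candidates, df], ignore_index=True)

    artifacts = candidates.loc[
        candidates["record_class"] != "dnm",
        ["chrom", "pos", "ref", "alt", "child_id", "family_id", "record_class", "aux_frac", "mosaic_parent"],
    ].reset_index(drop=True)
    candidates = candidates.sort_values(["child_id", "chrom", "pos", "alt"], kind="stable").reset_index(drop=True)
    cohort.candidates = candidates
    cohort.artifacts = artifacts
    return candidates, artifacts


# ---------------------------------------------------------------------------
# validation readouts


def simulate_validation_readouts(cohort: Cohort) -> pd.DataFrame:
    """Deep-resequencing (~300X) readouts for baited candidates.

    True DNMs read out at proband AAF ~ 0.5 with near-zero parental AAF;
    parental mosaics reproduce the parent's mosaic fraction; noise-class
    records stay at a low proband AAF, so each artifact class fails its
    corresponding validation threshold with high probability.
    """
    config = cohort.config
    rng = config.rng(3)
    cand = cohort.candidates
    if cand is None:
        raise ValueError("run simulate_discovery_calls first")
    if len(cand) == 0:
        return pd.DataFrame(
            columns=["chrom", "pos", "alt", "child_id", "proband_depth", "proband_aaf", "father_aaf", "mother_aaf"]
        )
    known = cand["record_class"].isin(["dnm", "parental_mosaic", "seq_noise", "recurrent"])
    if not known.all():
        bad = cand.loc[~known].iloc[0]
        raise ValueError(
            f"candidate {bad['child_id']}:{bad['chrom']}:{bad['pos']} is neither truth nor a known artifact"
        )

    baited = cand[rng.random(len(cand)) < config.bait_success_rate].copy()
    n = len(baited)
    vd = config.validation_depth_mean

    depth = rng.poisson(vd, size=n)
    bad = depth <= 10
    while bad.any():
        depth[bad] = rng.poisson(vd, size=int(bad.sum()))
        bad = depth <= 10
    f_depth = np.maximum(rng.poisson(vd, size=n), 1)
    m_depth = np.maximum(rng.poisson(vd, size=n), 1)

    cls = baited["record_class"].to_numpy()
    aux = baited["aux_frac"].to_numpy(dtype=float)
    realish = (cls == "dnm") | (cls == "parental_mosaic") | (cls == "recurrent")

    alt_reads = np.empty(n, dtype=int)
    alt_reads[realish] = rng.binomial(depth[realish], 0.5)
    # conditioning: a true het at 300X essentially never reads out below 0.3,
    # so resampling the residual tail keeps truth recoverable by construction
    bad = realish & (alt_reads / depth <= 0.3)
    while bad.any():
        alt_reads[bad] = rng.binomial(depth[bad], 0.5)
        bad = realish & (alt_reads / depth <= 0.3)
    noise = ~realish
    noise_frac = np.where(np.isnan(aux), 0.1, aux)
    alt_reads[noise] = rng.binomial(depth[noise], noise_frac[noise])

    f_alt = rng.binomial(f_depth, 0.001)
    m_alt = rng.binomial(m_depth, 0.001)
    mos = cls == "parental_mosaic"
    side = baited["mosaic_parent"].to_numpy()
    sel = mos & (side == "father")
    f_alt[sel] = rng.binomial(f_depth[sel], aux[sel])
    sel = mos & (side == "mother")
    m_alt[sel] = rng.binomial(m_depth[sel], aux[sel])

    out = pd.DataFrame(
        {
            "chrom": baited["chrom"].to_numpy(),
            "pos": baited["pos"].to_numpy(),
            "alt": baited["alt"].to_numpy(),
            "child_id": baited["child_id"].to_numpy(),
            "proband_depth": depth,
            "proband_aaf": alt_reads / depth,
            "father_aaf": f_alt / f_depth,
            "mother_aaf": m_alt / m_depth,
        }
    )
    cohort.readouts = out
    return out


# ---------------------------------------------------------------------------
# phase-informative fragments


def simulate_fragments(
    dnms: pd.DataFrame,
    config: SimConfig,
    phaseable_fraction: float | None = None,
    mean_fragments: float = 3.0,
    wrong_parent_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Informative heterozygous sites and linked read fragments for phasing.

    A ``phaseable_fraction`` of DNMs receives one nearby informative site
    (father and mother homozygous for different alleles, child heterozygous)
    and 1 + Poisson(mean_fragments - 1) alt-carrying fragments linking the DNM
    alt to the haplotype of the true parent of origin; an equal-rate set of
    reference-carrying fragments links the other haplotype.  Returns
    (sites, fragments); sites carry the trio genotypes.
    """
    rng = config.rng(4)
    if phaseable_fraction is None:
        phaseable_fraction = config.phaseable_fraction
    sel = dnms[rng.random(len(dnms)) < phaseable_fraction]
    site_rows, frag_rows = [], []
    frag_id = 0
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]
    for r in sel.itertuples(index=False):
        key = f"{r.child_id}:{r.chrom}:{r.pos}:{r.alt}"
        fa, mo = pairs[int(rng.integers(len(pairs)))]
        if rng.random() < 0.5:
            fa, mo = mo, fa
        offset = int(rng.integers(50, 401)) * (1 if rng.random() < 0.5 else -1)
        site_pos = max(2, int(r.pos) + offset)
        site_rows.append(
            {
                "dnm_key": key,
                "child_id": r.child_id,
                "family_id": r.family_id,
                "chrom": r.chrom,
                "site_pos": site_pos,
                "child_gt": f"{fa}/{mo}",
                "father_gt": f"{fa}/{fa}",
                "mother_gt": f"{mo}/{mo}",
                "distance": abs(offset),
            }
        )
        true_allele = fa if r.parent_of_origin == "paternal" else mo
        other_allele = mo if r.parent_of_origin == "paternal" else fa
        n_alt = 1 + int(rng.poisson(max(mean_fragments - 1, 0)))
        for _ in range(n_alt):
            allele = true_allele if rng.random() >= wrong_parent_rate else other_allele
            frag_rows.append(
                {
                    "fragment_id": f"frag{frag_id:07d}",
                    "dnm_key": key,
                    "dnm_allele": r.alt,
                    "site_pos": site_pos,
                    "site_allele": allele,
                }
            )
            frag_id += 1
        for _ in range(int(rng.poisson(max(mean_fragments - 1, 0)))):
            frag_rows.append(
                {
                    "fragment_id": f"frag{frag_id:07d}",
                    "dnm_key": key,
                    "dnm_allele": r.ref,
                    "site_pos": site_pos,
                    "site_allele": other_allele,
                }
            )
            frag_id += 1
    sites = pd.DataFrame(
        site_rows,
        columns=["dnm_key", "child_id", "family_id", "chrom", "site_pos",
                 "child_gt", "father_gt", "mother_gt", "distance"],
    )
    frags = pd.DataFrame(
        frag_rows, columns=["fragment_id", "dnm_key", "dnm_allele", "site_pos", "site_allele"]
    )
    return sites, frags


# ---------------------------------------------------------------------------
# reference catalog fixtures


def make_reference_catalogs(
    n_sigs: int,
    sparsity: float = 0.2,
    seed: int = 0,
    max_pairwise_cosine: float = 0.9,
    max_retries: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random sparse signature catalogs: a 96-channel set and its 192-channel
    strand-resolved twin.

    Signatures are Dirichlet draws on random channel subsets, rejected until
    every pair's cosine is below ``max_pairwise_cosine`` so downstream
    decomposition stays identifiable.  The 192-channel twin splits each
    channel over transcribed (T:) and untranscribed (U:) strands such that
    dropping the U strand and renormalising recovers the 96-channel catalog
    exactly.
    """
    if n_sigs < 2:
        raise ValueError("n_sigs must be >= 2")
    rng = np.random.default_rng(seed)
    k = max(4, int(round(sparsity * 96)))
    sigs = []
    tries = 0
    while len(sigs) < n_sigs:
        tries += 1
        if tries > max_retries:
            raise RuntimeError(
                f"could not draw {n_sigs} signatures with pairwise cosine < {max_pairwise_cosine}"
            )
        v = np.zeros(96)
        support = rng.choice(96, size=k, replace=False)
        v[support] = rng.dirichlet(np.ones(k))
        if all(_cos(v, s) < max_pairwise_cosine for s in sigs):
            sigs.append(v)
    names = [f"FIX{i + 1}" for i in range(n_sigs)]
    cat96 = pd.DataFrame(np.stack(sigs, axis=1), index=list(CHANNELS_96), columns=names)
    cat96.index.name = "Type"

    # strand split: T rows proportional to the 96 twin, U rows perturbed
    t_part = cat96.to_numpy() * 0.5
    noise = rng.lognormal(0, 0.4, size=t_part.shape)
    u_raw = cat96.to_numpy() * noise
    u_part = u_raw / u_raw.sum(axis=0, keepdims=True) * 0.5
    rows = []
    data = []
    for i, ch in enumerate(CHANNELS_96):
        rows.append(f"T:{ch}")
        data.append(t_part[i])
    for i, ch in enumerate(CHANNELS_96):
        rows.append(f"U:{ch}")
        data.append(u_part[i])
    cat192 = pd.DataFrame(np.stack(data), index=rows, columns=names)
    cat192.index.name = "Type"
    return cat96, cat192


def _cos(u, v):
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
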