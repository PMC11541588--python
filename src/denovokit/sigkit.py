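"""Single-base-substitution (SBS) spectrum and mutational-signature toolkit.

Implements the 96-channel trinucleotide convention (pyrimidine reference
strand), spectrum-matrix construction from de novo SNV tables, paternal-age
quartile stratification, a stability-selected KL-NMF signature extractor,
and greedy NNLS decomposition of an extracted signature against reference
catalogs scored by cosine similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SUBSTITUTIONS",
    "CHANNELS_96",
    "CPG_CHANNELS",
    "classify_substitution",
    "build_matrix",
    "stratify_by_age_quartile",
    "extract_signature",
    "ExtractionResult",
    "cosine",
    "decompose",
    "DecompositionResult",
    "collapse_strand",
    "best_match",
    "read_catalog",
    "write_catalog",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Canonical channel order: substitution-major, flanks lexicographic.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in _BASES for three in _BASES
)

#: The four CpG-motif C>T channels (ACG, CCG, GCG, TCG contexts).
CPG_CHANNELS = tuple(f"{five}[C>T]G" for five in _BASES)

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _fetch_context(genome, chrom: str, pos: int) -> str:
    """Trinucleotide centred on 1-based ``pos``; genome is a mapping or pyfaidx.Fasta."""
    seq = genome[chrom]
    if pos < 2 or pos > len(seq) - 1:
        raise ValueError(f"position {chrom}:{pos} lacks a full trinucleotide context")
    tri = str(seq[pos - 2 : pos + 1]).upper()
    if len(tri) != 3:
        raise ValueError(f"position {chrom}:{pos} lacks a full trinucleotide context")
    return tri


def classify_substitution(chrom: str, pos: int, ref: str, alt: str, genome) -> str | None:
    """Assign an SNV to its pyrimidine-strand 96-channel label.

    Purine-reference sites are reverse complemented so the reported reference
    base is C or T.  Returns ``None`` for contexts containing N (caller routes
    those to an unclassifiable bin); raises on a ref/genome mismatch.
    """
    ref, alt = ref.upper(), alt.upper()
    tri = _fetch_context(genome, chrom, pos)
    if tri[1] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: genome has {tri[1]!r}, table says {ref!r}"
        )
    if "N" in tri or alt == "N":
        return None
    if ref in "AG":
        tri = revcomp(tri)
        alt = _COMPLEMENT[alt]
    label = f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"
    if label not in _CHANNEL_INDEX:
        raise ValueError(f"not a substitution at {chrom}:{pos}: {ref}>{alt}")
    return label


@dataclass
class Spectrum:
    """A 96 x S count matrix in canonical channel order.

    ``counts`` rows follow :data:`CHANNELS_96`; ``n_unclassifiable`` counts
    sites dropped for N contexts; ``cpg_ct_counts`` is the per-sample subtotal
    over the four N[C>T]G channels.
    """

    counts: pd.DataFrame
    n_unclassifiable: int = 0

    @property
    def cpg_ct_counts(self) -> pd.Series:
        return self.counts.loc[list(CPG_CHANNELS)].sum(axis=0)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def pooled(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("Type").to_csv(path, sep="\t")


def build_matrix(
    dnms: pd.DataFrame,
    genome,
    grouping: str = "cohort",
    group_col: str | None = None,
) -> Spectrum:
    """Count validated SNVs into the 96 channels.

    ``dnms`` needs columns chrom/pos/ref/alt plus family_id/child_id as the
    grouping demands; ``grouping`` is one of cohort, per_family, per_child or
    custom (then ``group_col`` names the column).
    """
    col = {
        "cohort": None,
        "per_family": "family_id",
        "per_child": "child_id",
        "custom": group_col,
    }[grouping]
    if grouping == "custom" and col is None:
        raise ValueError("grouping='custom' requires group_col")

    if "channel" in dnms.columns:
        channels = dnms["channel"]
        n_bad = int(channels.isna().sum())
    else:
        labels = [
            classify_substitution(r.chrom, int(r.pos), r.ref, r.alt, genome)
            for r in dnms.itertuples(index=False)
        ]
        channels = pd.Series(labels, index=dnms.index, dtype=object)
        n_bad = sum(1 for x in labels if x is None)

    ok = channels.notna()
    cat = pd.Categorical(channels[ok], categories=list(CHANNELS_96))
    if col is None:
        counts = pd.DataFrame({"cohort": pd.Series(cat).value_counts(sort=False)})
        counts.index = list(CHANNELS_96)
    else:
        tab = pd.crosstab(cat, dnms.loc[ok, col], dropna=False)
        counts = tab.reindex(list(CHANNELS_96), fill_value=0)
        counts.columns = [str(c) for c in counts.columns]
    counts = counts.astype(int)
    counts.index.name = "Type"
    return Spectrum(counts=counts, n_unclassifiable=n_bad)


def stratify_by_age_quartile(
    dnms: pd.DataFrame, pedigrees: pd.DataFrame, genome=None
) -> tuple[Spectrum, tuple[float, float]]:
    """Spectra for children of the youngest (Q1) and oldest (Q4) fathers.

    Children — not SNVs — are partitioned by paternal age at birth, so sibling
    spectra are never split across quartiles.  Returns a two-column Spectrum
    (Q1, Q4) and the (lower, upper) quartile boundary ages.
    """
    ages = pedigrees.set_index("child_id")["paternal_age"]
    if len(ages) < 4:
        raise ValueError("age-quartile stratification needs at least 4 children")
    lo, hi = float(np.quantile(ages, 0.25)), float(np.quantile(ages, 0.75))
    if lo == hi:
        raise ValueError("degenerate age distribution: Q1 and Q4 boundaries coincide")
    q1_children = set(ages.index[ages < lo])
    q4_children = set(ages.index[ages > hi])
    sub = dnms[dnms["child_id"].isin(q1_children | q4_children)].copy()
    sub["age_quartile"] = np.where(sub["child_id"].isin(q1_children), "Q1", "Q4")
    spec = build_matrix(sub, genome, grouping="custom", group_col="age_quartile")
    counts = spec.counts.reindex(columns=["Q1", "Q4"], fill_value=0)
    return Spectrum(counts=counts, n_unclassifiable=spec.n_unclassifiable), (lo, hi)


# ---------------------------------------------------------------------------
# cosine / decomposition


def cosine(u, v) -> float:
    """Cosine similarity of two non-negative spectra (1 = identical shape)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(u @ v / (nu * nv))


@dataclass
class DecompositionResult:
    """Outcome of greedy NNLS refitting against a reference catalog."""

    signatures: list[str]
    weights: np.ndarray  # L1-normalised contributions, aligned to `signatures`
    reconstruction: np.ndarray
    cosine: float
    trace: list[tuple[str, float]] = field(default_factory=list)  # (added sig, cosine after)

    def contributions(self) -> pd.Series:
        return pd.Series(self.weights, index=self.signatures, name="contribution")

    def to_dict(self) -> dict:
        return {
            "signatures": self.signatures,
            "weights": [float(w) for w in self.weights],
            "cosine": self.cosine,
            "trace": [{"signature": s, "cosine": c} for s, c in self.trace],
        }


def _nnls_fit(target: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, _ = nnls(cols, target)
    return w, cols @ w


def decompose(
    target,
    catalog: pd.DataFrame,
    add_tol: float = 0.01,
    prune_tol: float = 0.01,
) -> DecompositionResult:
    """Express ``target`` as a non-negative mixture of catalog signatures.

    Greedy forward selection: at each step the signature whose inclusion (after
    an NNLS re-solve over the selected set) most increases the cosine between
    target and reconstruction is added; stops when the best gain < ``add_tol``.
    A backward pass prunes any signature whose removal costs < ``prune_tol``
    cosine.  Weights are the L1-normalised NNLS coefficients.
    """
    t = np.asarray(target, dtype=float)
    if t.ndim != 1 or np.any(t < 0):
        raise ValueError("target must be a non-negative vector")
    s = t.sum()
    if s <= 0:
        raise ValueError("target has zero mass")
    t = t / s

    cat = catalog.copy().astype(float)
    sums = cat.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        warnings.warn("catalog columns not normalised; renormalising", stacklevel=2)
        cat = cat / sums

    names = list(cat.columns)
    mat = cat.to_numpy()

    selected: list[int] = []
    trace: list[tuple[str, float]] = []
    best_cos = -np.inf
    while True:
        c_best, cand = -np.inf, None
        for j in range(mat.shape[1]):
            if j in selected:
                continue
            _, rec = _nnls_fit(t, mat[:, selected + [j]])
            if rec.sum() == 0:
                continue
            c = cosine(t, rec)
            if c > c_best:
                c_best, cand = c, j
        if cand is None:
            break
        if selected and c_best - best_cos < add_tol:
            break
        selected.append(cand)
        best_cos = c_best
        trace.append((names[cand], c_best))
        if len(selected) == mat.shape[1]:
            break

    # backward prune: drop signatures that buy < prune_tol cosine
    changed = True
    while changed and len(selected) > 1:
        changed = False
        for j in list(selected):
            rest = [k for k in selected if k != j]
            _, rec = _nnls_fit(t, mat[:, rest])
            if rec.sum() > 0 and best_cos - cosine(t, rec) < prune_tol:
                selected = rest
                _, rec = _nnls_fit(t, mat[:, selected])
                best_cos = cosine(t, rec)
                changed = True
                break

    w, rec = _nnls_fit(t, mat[:, selected])
    keep = w > 0
    sel_names = [names[j] for j, k in zip(selected, keep) if k]
    w = w[keep]
    weights = w / w.sum()
    return DecompositionResult(
        signatures=sel_names,
        weights=weights,
        reconstruction=rec,
        cosine=float(best_cos),
        trace=trace,
    )


def best_match(target, catalog: pd.DataFrame) -> pd.DataFrame:
    """Rank every catalog signature by cosine similarity to ``target``.

    Descending cosine; ties broken by signature name so the ranking is stable.
    """
    rows = [(name, cosine(target, catalog[name].to_numpy())) for name in catalog.columns]
    df = pd.DataFrame(rows, columns=["signature", "cosine"])
    return df.sort_values(["cosine", "signature"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# strand-resolved catalogs


def collapse_strand(catalog192: pd.DataFrame, mode: str = "drop", keep: str = "T") -> pd.DataFrame:
    """Collapse a 192-row strand-resolved catalog to 96 channels.

    Row labels are ``"T:A[C>A]A"`` / ``"U:A[C>A]A"`` (transcribed /
    untranscribed strand).  ``mode='drop'`` keeps the ``keep`` strand's rows
    and renormalises; ``mode='sum'`` adds complementary rows then renormalises.
    """
    if mode not in ("drop", "sum"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = list(catalog192.index)
    parsed = []
    for lab in labels:
        strand, _, chan = lab.partition(":")
        if strand not in ("T", "U") or chan not in _CHANNEL_INDEX:
            raise ValueError(f"malformed strand-resolved label {lab!r}")
        parsed.append((strand, chan))
    by_strand: dict[str, dict[str, int]] = {"T": {}, "U": {}}
    for i, (strand, chan) in enumerate(parsed):
        by_strand[strand][chan] = i
    unpaired = sorted(set(by_strand["T"]) ^ set(by_strand["U"]))
    if unpaired or len(by_strand["T"]) != 96:
        raise ValueError(f"unpaired or missing strand rows: {unpaired or 'incomplete set'}")

    if mode == "drop":
        rows = [by_strand[keep][c] for c in CHANNELS_96]
        out = catalog192.iloc[rows].copy()
    else:
        t = catalog192.iloc[[by_strand["T"][c] for c in CHANNELS_96]].to_numpy()
        u = catalog192.iloc[[by_strand["U"][c] for c in CHANNELS_96]].to_numpy()
        out = pd.DataFrame(t + u, columns=catalog192.columns)
    out.index = list(CHANNELS_96)
    out.index.name = "Type"
    out = out / out.sum(axis=0)
    out.attrs["strand_collapse_mode"] = mode
    return out


# ---------------------------------------------------------------------------
# catalog I/O (COSMIC-style text dialect)


def read_catalog(path, strict_order: bool = True) -> pd.DataFrame:
    """Read a tab-delimited catalog: a Type column of 96 labels + one column per signature.

    With ``strict_order`` (default) files whose rows are not in canonical order
    are rejected rather than silently reordered; pass ``strict_order=False`` to
    accept any complete permutation (reindexed, with a warning).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = list(df.index)
    if sorted(labels) != sorted(CHANNELS_96):
        missing = set(CHANNELS_96) - set(labels)
        raise ValueError(f"catalog does not carry exactly the 96 channels (missing: {sorted(missing)[:5]}...)")
    if labels != list(CHANNELS_96):
        if strict_order:
            raise ValueError("catalog rows are not in canonical channel order (strict_order=True)")
        warnings.warn("reindexing catalog rows to canonical channel order", stacklevel=2)
        df = df.reindex(list(CHANNELS_96))
    df.index.name = "Type"
    return df.astype(float)


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.rename_axis("Type").to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# stability-selected NMF extraction


@dataclass
class ExtractionResult:
    """De novo signature extraction outcome.

    ``signatures`` holds the consensus signatures (96 x k, columns L1-normed)
    for the selected k; ``stats`` reports per-k mean silhouette and relative
    reconstruction error over bootstrap replicates.
    """

    signatures: pd.DataFrame
    selected_k: int
    stats: pd.DataFrame
    seed: int | None = None

    def primary(self) -> np.ndarray:
        """The dominant extracted signature (highest total exposure)."""
        return self.signatures.iloc[:, 0].to_numpy()


def _bootstrap_matrix(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    boot = np.empty_like(counts, dtype=float)
    probs = counts / np.maximum(counts.sum(axis=0, keepdims=True), 1)
    for j in range(counts.shape[1]):
        n = int(counts[:, j].sum())
        boot[:, j] = rng.multinomial(n, probs[:, j]) if n > 0 else 0.0
    return boot


def extract_signature(
    matrix,
    k_range=(1, 2, 3),
    n_replicates: int = 20,
    seed: int | None = None,
    error_tol_factor: float = 1.2,
    max_iter: int = 2000,
) -> ExtractionResult:
    """Extract de novo signatures by bootstrap-stabilised KL-NMF.

    For each k in ``k_range`` the count matrix is resampled ``n_replicates``
    times (per-column multinomial), factorised by multiplicative-update NMF
    under the KL objective, and the replicate signatures are clustered into k
    consensus signatures; stability is the mean silhouette of that clustering
    (defined as 1 for k=1, where the factorisation is the closed-form
    normalised pooled spectrum).  The selected k maximises silhouette among
    those whose reconstruction error is within ``error_tol_factor`` of the
    best k's error; ties go to the smaller k.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import NMF
    from sklearn.metrics import silhouette_score

    if isinstance(matrix, Spectrum):
        counts = matrix.counts
    elif isinstance(matrix, pd.DataFrame):
        counts = matrix
    else:
        counts = pd.DataFrame(np.asarray(matrix, dtype=float))
    X = counts.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("count matrix must be non-negative")
    if X.sum() == 0:
        raise ValueError("count matrix is all zero")
    norm_x = np.linalg.norm(X)
    rng = np.random.default_rng(seed)

    ks = sorted(set(int(k) for k in k_range))
    if min(ks) < 1 or max(ks) > X.shape[1]:
        raise ValueError("k_range must lie within [1, n_samples]")

    records = []
    consensus: dict[int, np.ndarray] = {}
    for k in ks:
        if k == 1:
            sig = X.sum(axis=1)
            sig = sig / sig.sum()
            consensus[1] = sig[:, None]
            # rank-1 reconstruction keeps column totals
            recon = np.outer(sig, X.sum(axis=0))
            err = np.linalg.norm(X - recon) / norm_x
            records.append({"k": 1, "silhouette": 1.0, "rel_error": err})
            continue

        sigs = []
        for _ in range(n_replicates):
            B = _bootstrap_matrix(X, rng)
            model = NMF(
                n_components=k,
                beta_loss="kullback-leibler",
                solver="mu",
                init="random",
                max_iter=max_iter,
                random_state=int(rng.integers(2**31 - 1)),
                tol=1e-6,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                W = model.fit_transform(B)
            W = W / np.maximum(W.sum(axis=0, keepdims=True), 1e-300)
            sigs.append(W)
        S = np.hstack(sigs)  # 96 x (k * n_replicates)
        unit = S / np.maximum(np.linalg.norm(S, axis=0, keepdims=True), 1e-300)
        km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(unit.T)
        try:
            sil = float(silhouette_score(unit.T, labels, metric="cosine"))
        except ValueError:
            sil = -1.0
        cons = np.stack(
            [S[:, labels == c].mean(axis=1) if np.any(labels == c) else np.zeros(S.shape[0]) for c in range(k)],
            axis=1,
        )
        cons = cons / np.maximum(cons.sum(axis=0, keepdims=True), 1e-300)
        # refit exposures on the original matrix to score reconstruction
        H = np.stack([nnls(cons, X[:, j])[0] for j in range(X.shape[1])], axis=1)
        err = np.linalg.norm(X - cons @ H) / norm_x
        consensus[k] = cons
        records.append({"k": k, "silhouette": sil, "rel_error": err})

    stats = pd.DataFrame(records).set_index("k")
    best_err = stats["rel_error"].min()
    feasible = stats[stats["rel_error"] <= error_tol_factor * max(best_err, 1e-12)]
    selected_k = int(feasible.sort_values(["silhouette", "k"], ascending=[False, True]).index[0])

    cons = consensus[selected_k]
    # order columns by total exposure against the original matrix
    H = np.stack([nnls(cons, X[:, j])[0] for j in range(X.shape[1])], axis=1)
    order = np.argsort(-H.sum(axis=1), kind="stable")
    cons = cons[:, order]
    sig_df = pd.DataFrame(
        cons,
        index=list(CHANNELS_96) if X.shape[0] == 96 else counts.index,
        columns=[f"SBS96{chr(ord('A') + i)}" for i in range(selected_k)],
    )
    sig_df.index.name = "Type"
    return ExtractionResult(signatures=sig_df, selected_k=selected_k, stats=stats, seed=seed)
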