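"""Genome-scale micFFL mining: motif enumeration, degree-preserving
randomization with z-scores, PWM promoter scanning and the binomial
protein-protein overlap test.

The regulatory network is bipartite-by-layer: a post-transcriptional layer
of miRNA->gene edges (each annotated with how many of the supporting
databases confirm it, 1-4) and a transcriptional layer of TF->gene edges.
A micFFL instance is a triple (miRNA m, TF f, target t) with m->f, m->t and
f->t all present and f != t.  Enrichment is assessed by reshuffling one
layer at a time, keeping each regulator's out-degree fixed, and comparing
the observed motif count against the permutation null through
z = (N_real - mu) / sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import binom

from .errors import ConfigurationError

__all__ = [
    "RegulatoryNetwork",
    "FFLInstance",
    "EnrichmentResult",
    "PFM",
    "ScanResult",
    "Interval",
    "enumerate_micffls",
    "shuffle_mirna_layer",
    "shuffle_tf_layer",
    "enrichment_test",
    "pwm_scan",
    "promoter_window",
    "overlap_binomial_test",
    "read_jaspar",
]

MIRNA_COLUMNS = ("mirna", "gene", "support")
TF_COLUMNS = ("tf", "gene", "evidence")


class FFLInstance(NamedTuple):
    """One micFFL triple with the database support of its miRNA links."""

    mirna: str
    tf: str
    target: str
    support_tf: int  # support of the miRNA -> TF link
    support_t: int   # support of the miRNA -> target link


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Two regulatory layers over a declared gene universe.

    ``mirna_edges`` columns: mirna, gene, support (1-4);
    ``tf_edges`` columns: tf, gene, evidence (free-form tag).
    The gene universe is the pool degree-preserving shuffles draw from.
    """

    mirna_edges: pd.DataFrame
    tf_edges: pd.DataFrame
    genes: frozenset[str]

    def __post_init__(self) -> None:
        me = pd.DataFrame(self.mirna_edges, columns=list(MIRNA_COLUMNS))
        te = pd.DataFrame(self.tf_edges, columns=list(TF_COLUMNS))
        me["support"] = me["support"].astype(int)
        if me.duplicated(["mirna", "gene"]).any():
            raise ConfigurationError("duplicate miRNA->gene edges")
        if te.duplicated(["tf", "gene"]).any():
            raise ConfigurationError("duplicate TF->gene edges")
        if len(me) and not me["support"].between(1, 4).all():
            raise ConfigurationError("miRNA edge support must be in 1..4")
        genes = frozenset(self.genes)
        missing = (set(me["gene"]) | set(te["gene"])) - genes
        if missing:
            raise ConfigurationError(
                f"{len(missing)} edge endpoint(s) outside the gene universe, "
                f"e.g. {sorted(missing)[:3]}"
            )
        object.__setattr__(self, "mirna_edges", me.reset_index(drop=True))
        object.__setattr__(self, "tf_edges", te.reset_index(drop=True))
        object.__setattr__(self, "genes", genes)

    @classmethod
    def from_edges(
        cls,
        mirna_edges: Iterable[tuple],
        tf_edges: Iterable[tuple],
        genes: Iterable[str] | None = None,
    ) -> "RegulatoryNetwork":
        me = pd.DataFrame(list(mirna_edges), columns=list(MIRNA_COLUMNS))
        tf_rows = [t if len(t) == 3 else (*t, "na") for t in tf_edges]
        te = pd.DataFrame(tf_rows, columns=list(TF_COLUMNS))
        if genes is None:
            genes = set(me["gene"]) | set(te["gene"]) | set(te["tf"])
        return cls(me, te, frozenset(genes))

    @classmethod
    def from_tsv(cls, mirna_path, tf_path, genes_path=None) -> "RegulatoryNetwork":
        me = pd.read_csv(mirna_path, sep="\t", dtype={0: str, 1: str})
        me.columns = list(MIRNA_COLUMNS)[: len(me.columns)]
        te = pd.read_csv(tf_path, sep="\t", dtype=str)
        te.columns = list(TF_COLUMNS)[: len(te.columns)]
        if "evidence" not in te.columns:
            te["evidence"] = "na"
        genes = None
        if genes_path is not None:
            genes = set(pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str))
        return cls.from_edges(
            me.itertuples(index=False, name=None),
            te.itertuples(index=False, name=None),
            genes,
        )

    def to_tsv(self, mirna_path, tf_path) -> None:
        self.mirna_edges.to_csv(mirna_path, sep="\t", index=False)
        self.tf_edges.to_csv(tf_path, sep="\t", index=False)

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(self.mirna_edges["mirna"])

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(self.tf_edges["tf"])


def enumerate_micffls(
    net: RegulatoryNetwork, min_support: int = 1
) -> list[FFLInstance]:
    """All triples (m, f, t) with m->f, m->t, f->t present, f != t and both
    miRNA links supported by at least ``min_support`` databases.

    Join-based (pandas merges); equivalent to the brute-force triple loop.
    The result is sorted, hence independent of input edge order."""
    if not 1 <= int(min_support) <= 4:
        raise ValueError("min_support must be in 1..4")
    me = net.mirna_edges[net.mirna_edges["support"] >= int(min_support)]
    if me.empty or net.tf_edges.empty:
        return []
    m_to_tf = me.rename(columns={"gene": "tf", "support": "support_tf"})
    m_to_t = me.rename(columns={"gene": "target", "support": "support_t"})
    tf_t = net.tf_edges.rename(columns={"gene": "target"})[["tf", "target"]]
    triples = (
        m_to_tf.merge(tf_t, on="tf")
        .merge(m_to_t, on=["mirna", "target"])
        .query("tf != target")
    )
    out = [
        FFLInstance(r.mirna, r.tf, r.target, int(r.support_tf), int(r.support_t))
        for r in triples.itertuples(index=False)
    ]
    return sorted(out)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _shuffle_layer(
    edges: pd.DataFrame, source_col: str, universe: list[str], rng
) -> pd.DataFrame:
    pool = np.asarray(universe, dtype=object)
    rows = []
    for src, grp in edges.groupby(source_col, sort=True):
        k = len(grp)
        if k > pool.size:
            raise ConfigurationError(
                f"out-degree {k} of {src!r} exceeds universe size {pool.size}"
            )
        targets = rng.choice(pool, size=k, replace=False)
        rows.extend((src, t) for t in targets)
    return pd.DataFrame(rows, columns=[source_col, "gene"])


def shuffle_mirna_layer(net: RegulatoryNetwork, seed=0) -> RegulatoryNetwork:
    """Degree-preserving randomization of the post-transcriptional layer.

    Each miRNA's target set is replaced by a uniform sample without
    replacement from the gene universe of the same size; the TF layer is
    untouched.  Randomized edges carry maximal support (4): the null
    redistributes targets, not evidence, so every randomized triangle is
    counted regardless of the support filter applied to the observed
    network."""
    rng = _as_rng(seed)
    new = _shuffle_layer(net.mirna_edges, "mirna", sorted(net.genes), rng)
    new["support"] = 4
    return RegulatoryNetwork(new, net.tf_edges.copy(), net.genes)


def shuffle_tf_layer(net: RegulatoryNetwork, seed=0) -> RegulatoryNetwork:
    """Degree-preserving randomization of the transcriptional layer; the
    miRNA layer (including its support annotations) is untouched."""
    rng = _as_rng(seed)
    new = _shuffle_layer(net.tf_edges, "tf", sorted(net.genes), rng)
    new["evidence"] = "shuffled"
    return RegulatoryNetwork(net.mirna_edges.copy(), new, net.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed motif count against its degree-preserving permutation null."""

    n_real: int
    null_mean: float
    null_sd: float
    z: float | None               # None when the null is degenerate (sd = 0)
    p_upper: float                # empirical P(null >= N_real)
    p_lower: float                # empirical P(null <= N_real)
    n_perm: int
    layer: str
    null_counts: np.ndarray = field(repr=False)
    flags: tuple[str, ...] = ()


def enrichment_test(
    net: RegulatoryNetwork,
    layer: str,
    n_perm: int = 1000,
    min_support: int = 1,
    seed=0,
) -> EnrichmentResult:
    """Layer-wise degree-preserving enrichment z-score for the micFFL count.

    ``layer`` is "mirna" or "tf"; z = (N_real - mu)/sigma with mu, sigma
    the mean and standard deviation of the count over ``n_perm`` shuffled
    networks, and empirical tail p-values with the add-one correction."""
    if layer not in ("mirna", "tf"):
        raise ValueError("layer must be 'mirna' or 'tf'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = _as_rng(seed)
    shuffle = shuffle_mirna_layer if layer == "mirna" else shuffle_tf_layer
    n_real = len(enumerate_micffls(net, min_support))
    null = np.array([
        len(enumerate_micffls(shuffle(net, rng), min_support))
        for _ in range(int(n_perm))
    ])
    mu = float(null.mean())
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    flags: list[str] = []
    z: float | None
    if sd > 0:
        z = (n_real - mu) / sd
    else:
        z = None
        flags.append("degenerate_null")
    p_up = (1 + int((null >= n_real).sum())) / (n_perm + 1)
    p_lo = (1 + int((null <= n_real).sum())) / (n_perm + 1)
    return EnrichmentResult(
        n_real, mu, sd, z, p_up, p_lo, int(n_perm), layer, null, tuple(flags)
    )


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix (base counts per position) with its
    log-odds scoring form.

    ``counts`` has shape (4, width), rows in A, C, G, T order.  Scores are
    log2 of pseudocounted position frequencies over the background."""

    counts: np.ndarray
    pseudocount: float = 1.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    name: str = "pfm"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4:
            raise ValueError("counts must have shape (4, width)")
        if np.any(c < 0) or np.any(c.sum(axis=0) <= 0):
            raise ValueError("counts must be >= 0 with positive column sums")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or not math.isclose(bg.sum(), 1.0,
                                                                   rel_tol=1e-6):
            raise ValueError("background must be 4 positive frequencies summing to 1")
        object.__setattr__(self, "counts", c)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        freq = (self.counts + self.pseudocount) / (
            self.counts.sum(axis=0) + 4.0 * self.pseudocount
        )
        return np.log2(freq / np.asarray(self.background)[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.log_odds.argmax(axis=0))

    def reverse_complement(self) -> "PFM":
        return PFM(self.counts[::-1, ::-1].copy(), self.pseudocount,
                   self.background, self.name + "_rc")


def read_jaspar(path_or_handle) -> PFM:
    """Read the first motif of a JASPAR flat file via Bio.motifs."""
    from Bio import motifs

    if hasattr(path_or_handle, "read"):
        m = motifs.read(path_or_handle, "jaspar")
    else:
        with open(path_or_handle) as fh:
            m = motifs.read(fh, "jaspar")
    counts = np.array([m.counts[b] for b in _BASES], dtype=float)
    return PFM(counts, name=m.name or m.matrix_id or "pfm")


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int
    clipped: bool = False

    def __iter__(self):
        return iter((self.start, self.end))

    @property
    def length(self) -> int:
        return self.end - self.start


def promoter_window(
    tss: int, strand: str, upstream: int = 900, downstream: int = 100
) -> Interval:
    """Promoter interval around a transcription start site.

    1 kb by default: 900 bases upstream of the TSS to 100 bases after it,
    0-based half-open, mirrored on the minus strand.  Windows that would
    extend below coordinate 0 are clipped and flagged."""
    if tss < 0:
        raise ValueError(f"TSS must be >= 0, got {tss}")
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream + 1, tss + upstream + 1
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    clipped = start < 0
    return Interval(max(start, 0), end, clipped)


@dataclass(frozen=True)
class ScanResult:
    """PWM hits: (0-based window start, relative score) pairs."""

    hits: tuple[tuple[int, float], ...]
    flags: tuple[str, ...] = ()

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.hits)


def pwm_scan(pfm: PFM, promoter: str, rel_threshold: float = 0.7) -> ScanResult:
    """Scan a promoter sequence with a PFM's log-odds matrix.

    Each window's score is normalized to the relative scale
    (score - min) / (max - min) over the attainable range; windows with a
    relative score >= ``rel_threshold`` are reported at their 0-based start.
    Windows containing N (or any non-ACGT character) are skipped; a
    sequence shorter than the motif yields an empty, flagged result."""
    if not 0.0 < rel_threshold <= 1.0:
        raise ValueError("rel_threshold must be in (0, 1]")
    seq = promoter.upper()
    w = pfm.width
    if len(seq) < w:
        return ScanResult((), ("sequence_shorter_than_motif",))
    lo = pfm.log_odds
    span = pfm.max_score - pfm.min_score
    if span <= 0:
        return ScanResult((), ("degenerate_matrix",))
    codes = np.fromiter(
        (_BASE_INDEX.get(ch, -1) for ch in seq), dtype=np.int64, count=len(seq)
    )
    hits: list[tuple[int, float]] = []
    for pos in range(len(seq) - w + 1):
        window = codes[pos: pos + w]
        if np.any(window < 0):
            continue
        score = float(lo[window, np.arange(w)].sum())
        rel = (score - pfm.min_score) / span
        if rel >= rel_threshold:
            hits.append((pos, rel))
    return ScanResult(tuple(hits))


def overlap_binomial_test(n_hits: int, n_pairs: int, probability: float) -> float:
    """Upper-tail binomial P(X >= n_hits) for X ~ Binom(n_pairs, p).

    Used for the protein-protein interaction overlap of candidate TF-target
    pairs against a per-pair background probability."""
    if not 0 <= n_hits <= n_pairs:
        raise ValueError("need 0 <= n_hits <= n_pairs")
    if not 0.0 < probability < 1.0:
        raise ValueError("probability must be in (0, 1)")
    return float(binom.sf(n_hits - 1, n_pairs, probability))
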