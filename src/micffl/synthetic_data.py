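"""Synthetic inputs for every pipeline stage.

Three generators emulate the statistical structure of the data the analysis
consumes, each a pure function of (spec, seed):

* bipartite regulatory networks with controllable out-degree distributions
  and a planted number of micFFLs (or a depleted topology in which closing
  TF->T edges are removed wherever a miRNA co-targets the pair);
* kinetic parameter sets drawn log-uniformly from physiological ranges,
  accepted only if the miRNA-free steady state has plausible protein copy
  numbers;
* promoter sequences with motif occurrences embedded at known positions,
  emitted together with the ground truth so scans can be validated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .circuits import KineticParameters, save_parameters, get_topology
from .errors import ConfigurationError
from .motif_mining import PFM, RegulatoryNetwork, reverse_complement

__all__ = [
    "NetworkSpec",
    "ParameterSpec",
    "generate_network",
    "sample_parameters",
    "generate_promoters",
    "random_pfm",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Shape of a synthetic two-layer regulatory network.

    Degree distributions per layer: ``("fixed", k)``, ``("poisson", mean)``
    or ``("powerlaw", exponent)`` (heavy-tailed targetomes; miRNA default).
    ``n_planted_ffls`` closes TF->T links over co-targeted pairs;
    ``deplete`` instead removes every closing TF->T link so the network is
    anti-enriched for the motif.
    """

    n_mirnas: int = 30
    n_tfs: int = 15
    n_genes: int = 500
    mirna_degree: tuple[str, float] = ("powerlaw", 2.0)
    tf_degree: tuple[str, float] = ("poisson", 20.0)
    n_planted_ffls: int = 0
    deplete: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_tfs, self.n_genes) < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.deplete and self.n_planted_ffls:
            raise ConfigurationError("cannot both plant and deplete micFFLs")
        max_triples = self.n_mirnas * self.n_tfs * self.n_genes
        if self.n_planted_ffls > max_triples:
            raise ConfigurationError(
                f"cannot plant {self.n_planted_ffls} micFFLs: only "
                f"{max_triples} distinct triples exist"
            )


def _draw_degrees(rng: np.random.Generator, n: int, dist: tuple[str, float],
                  cap: int) -> np.ndarray:
    kind, param = dist
    if kind == "fixed":
        deg = np.full(n, int(param))
    elif kind == "poisson":
        deg = rng.poisson(param, size=n)
    elif kind == "powerlaw":
        deg = rng.zipf(param, size=n)
    else:
        raise ConfigurationError(f"unknown degree distribution {kind!r}")
    if np.any(deg > cap):
        deg = np.minimum(deg, cap)
    return deg.astype(int)


def generate_network(spec: NetworkSpec) -> tuple[RegulatoryNetwork, dict]:
    """Sample a network and return it with its ground truth.

    The truth dict records the planted triples (or the closing edges removed
    under depletion) so recovery-style tests in the mining stage can check
    the expected enrichment sign."""
    rng = np.random.default_rng(spec.seed)
    mirnas = [f"mir{i}" for i in range(spec.n_mirnas)]
    tfs = [f"tf{i}" for i in range(spec.n_tfs)]
    genes = [f"g{i}" for i in range(spec.n_genes)]
    universe = tfs + genes  # miRNAs may target TF genes and ordinary genes
    pool = np.asarray(universe, dtype=object)

    mirna_edges: dict[tuple[str, str], int] = {}
    for m, d in zip(mirnas, _draw_degrees(rng, len(mirnas), spec.mirna_degree,
                                          len(pool))):
        if d > pool.size:
            raise ConfigurationError("miRNA out-degree exceeds universe size")
        for g in rng.choice(pool, size=d, replace=False):
            mirna_edges[(m, g)] = int(rng.integers(1, 5))

    tf_edges: set[tuple[str, str]] = set()
    for f, d in zip(tfs, _draw_degrees(rng, len(tfs), spec.tf_degree,
                                       len(pool) - 1)):
        choices = pool[pool != f]
        for g in rng.choice(choices, size=min(d, choices.size), replace=False):
            tf_edges.add((f, g))

    truth: dict = {"planted": [], "removed_edges": [], "spec": dataclasses.asdict(spec)}

    if spec.n_planted_ffls:
        if not (mirnas and tfs and genes):
            raise ConfigurationError("planting requires miRNAs, TFs and genes")
        seen: set[tuple[str, str, str]] = set()
        budget = 100 * spec.n_planted_ffls + 100
        while len(truth["planted"]) < spec.n_planted_ffls and budget:
            budget -= 1
            triple = (
                mirnas[rng.integers(len(mirnas))],
                tfs[rng.integers(len(tfs))],
                universe[rng.integers(len(universe))],
            )
            m, f, t = triple
            if f == t or triple in seen:
                continue
            seen.add(triple)
            mirna_edges[(m, f)] = 4
            mirna_edges[(m, t)] = 4
            tf_edges.add((f, t))
            truth["planted"].append(list(triple))
        if len(truth["planted"]) < spec.n_planted_ffls:
            raise ConfigurationError(
                "could not place the requested number of planted micFFLs"
            )

    if spec.deplete:
        targets_of: dict[str, set[str]] = {}
        for (m, g) in mirna_edges:
            targets_of.setdefault(m, set()).add(g)
        closing = {
            (f, t)
            for (f, t) in tf_edges
            if any(f in tg and t in tg for tg in targets_of.values())
        }
        tf_edges -= closing
        truth["removed_edges"] = sorted(map(list, closing))

    net = RegulatoryNetwork.from_edges(
        [(m, g, s) for (m, g), s in sorted(mirna_edges.items())],
        [(f, g, "synthetic") for (f, g) in sorted(tf_edges)],
        universe,
    )
    return net, truth


@dataclass(frozen=True)
class ParameterSpec:
    """Log-uniform sampling ranges for the kinetic rate classes.

    Ranges are dimensionless (time in target-protein lifetimes); the
    defaults span the physiological orders of magnitude used across the
    analyses.  Each draw is accepted only if the miRNA-free (NM1) steady
    state puts both proteins inside ``protein_band`` copies per cell.
    """

    transcription: tuple[float, float] = (5.0, 50.0)
    translation: tuple[float, float] = (2.0, 20.0)
    mrna_degradation: tuple[float, float] = (2.0, 10.0)
    protein_degradation: tuple[float, float] = (0.5, 2.0)
    mirna_degradation: tuple[float, float] = (0.2, 2.0)
    complex_degradation: tuple[float, float] = (0.5, 5.0)
    k_on: tuple[float, float] = (0.01, 10.0)
    alpha: tuple[float, float] = (0.0, 1.0)
    hill_n: tuple[float, ...] = (1.0, 2.0, 4.0)
    hill_h: tuple[float, float] = (1.0, 20.0)
    protein_band: tuple[float, float] = (10.0, 1e5)
    max_retries: int = 200

    def __post_init__(self) -> None:
        for name in ("transcription", "translation", "mrna_degradation",
                     "protein_degradation", "mirna_degradation",
                     "complex_degradation", "k_on", "hill_h"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"range {name}=({lo}, {hi}) must be "
                                         "positive and ordered")


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return float(lo)
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_parameters(
    spec: ParameterSpec, n_sets: int, seed: int = 0
) -> list[KineticParameters]:
    """Draw ``n_sets`` physiological parameter sets (rejection sampling on
    the protein-copy plausibility band).  Deterministic given (spec, seed)."""
    from .deterministic import steady_state_given_free_mirna

    rng = np.random.default_rng(seed)
    out: list[KineticParameters] = []
    lo, hi = spec.protein_band
    for _ in range(n_sets):
        for attempt in range(spec.max_retries):
            p = KineticParameters(
                k_mi=_loguniform(rng, *spec.transcription),
                g_mi=_loguniform(rng, *spec.mirna_degradation),
                k_mtf=_loguniform(rng, *spec.transcription),
                g_mtf=_loguniform(rng, *spec.mrna_degradation),
                k_ptf=_loguniform(rng, *spec.translation),
                g_ptf=_loguniform(rng, *spec.protein_degradation),
                k_mt=_loguniform(rng, *spec.transcription),
                g_mt=_loguniform(rng, *spec.mrna_degradation),
                k_pt=_loguniform(rng, *spec.translation),
                g_pt=1.0,  # rescaled time unit
                k_on_tf=_loguniform(rng, *spec.k_on),
                k_on_t=_loguniform(rng, *spec.k_on),
                g_ctf=_loguniform(rng, *spec.complex_degradation),
                g_ct=_loguniform(rng, *spec.complex_degradation),
                alpha=float(rng.uniform(*spec.alpha)),
                hill_n=float(rng.choice(spec.hill_n)),
                hill_h=_loguniform(rng, *spec.hill_h),
            )
            ss = steady_state_given_free_mirna(0.0, p, "NM1")
            if lo <= ss["pTF"] <= hi and lo <= ss["pT"] <= hi:
                out.append(p)
                break
        else:
            raise ConfigurationError(
                f"retry budget ({spec.max_retries}) exhausted: ranges "
                f"transcription={spec.transcription}, "
                f"translation={spec.translation} rarely land in the "
                f"plausibility band {spec.protein_band}"
            )
    return out


def random_pfm(width: int = 8, seed: int = 0, total: int = 40,
               concentration: float = 0.85, name: str = "synthetic") -> PFM:
    """Random informative PFM: per column one dominant base holding
    ``concentration`` of the counts."""
    rng = np.random.default_rng(seed)
    counts = np.zeros((4, width))
    for j in range(width):
        dom = rng.integers(4)
        rest = total * (1 - concentration) / 3.0
        counts[:, j] = rest
        counts[dom, j] = total * concentration
    return PFM(np.rint(counts), name=name)


def generate_promoters(
    pfm: PFM,
    n_sequences: int,
    length: int = 1000,
    embed_positions: dict[int, list[tuple[int, str]]] | None = None,
    gc: float = 0.5,
    seed: int = 0,
    embed: str = "consensus",
) -> tuple[list[SeqRecord], list[dict]]:
    """I.i.d. background sequences with motif occurrences embedded.

    ``embed_positions`` maps sequence index -> list of (position, strand)
    sites; ``embed`` is "consensus" (the PFM consensus) or "sample" (one
    realization drawn column-wise from the PFM).  Returns the FASTA records
    and the ground-truth table of embedded sites."""
    if not 0.0 < gc < 1.0:
        raise ConfigurationError("GC content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    embed_positions = embed_positions or {}
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    records: list[SeqRecord] = []
    truth: list[dict] = []
    for i in range(n_sequences):
        seq = rng.choice(bases, size=length, p=probs)
        sites = sorted(embed_positions.get(i, ()))
        occupied: list[tuple[int, int]] = []
        for pos, strand in sites:
            if pos < 0 or pos + pfm.width > length:
                raise ConfigurationError(
                    f"embedding at {pos} leaves the motif outside sequence {i}"
                )
            if any(pos < e and pos + pfm.width > s for s, e in occupied):
                raise ConfigurationError(
                    f"overlapping embeddings at {pos} in sequence {i}"
                )
            occupied.append((pos, pos + pfm.width))
            if embed == "consensus":
                motif = pfm.consensus
            elif embed == "sample":
                freq = pfm.counts / pfm.counts.sum(axis=0)
                motif = "".join(
                    str(rng.choice(bases, p=freq[:, j])) for j in range(pfm.width)
                )
            else:
                raise ConfigurationError(f"unknown embed mode {embed!r}")
            if strand == "-":
                motif = reverse_complement(motif)
            elif strand != "+":
                raise ConfigurationError(f"strand must be '+' or '-', got {strand!r}")
            seq[pos: pos + pfm.width] = list(motif)
            truth.append({"sequence": f"prom{i}", "position": int(pos),
                          "strand": strand})
        records.append(
            SeqRecord(Seq("".join(seq)), id=f"prom{i}", description="")
        )
    return records, truth


def write_fixture_bundle(
    directory,
    network_spec: NetworkSpec | None = None,
    parameter_spec: ParameterSpec | None = None,
    topology: str = "MICFFL",
    pfm: PFM | None = None,
    n_promoters: int = 5,
    seed: int = 0,
) -> dict:
    """Write a complete fixture directory: mirna_edges.tsv / tf_edges.tsv,
    params.yaml, promoters.fasta and truth.json (ground-truth side channel).
    Returns the truth dict."""
    from Bio import SeqIO

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    network_spec = network_spec or NetworkSpec(seed=seed)
    parameter_spec = parameter_spec or ParameterSpec()
    pfm = pfm or random_pfm(seed=seed)

    net, truth = generate_network(network_spec)
    net.to_tsv(directory / "mirna_edges.tsv", directory / "tf_edges.tsv")

    params = sample_parameters(parameter_spec, 1, seed=seed)[0]
    save_parameters(directory / "params.yaml", params, get_topology(topology))

    rng = np.random.default_rng(seed)
    embed = {
        i: [(int(rng.integers(0, 1000 - pfm.width)), "+")]
        for i in range(min(2, n_promoters))
    }
    records, sites = generate_promoters(pfm, n_promoters, embed_positions=embed,
                                        seed=seed)
    SeqIO.write(records, directory / "promoters.fasta", "fasta")

    truth_all = {"network": truth, "embedded_sites": sites,
                 "pfm_consensus": pfm.consensus, "seed": seed}
    (directory / "truth.json").write_text(json.dumps(truth_all, indent=2))
    return truth_all
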