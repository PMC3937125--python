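"""Circuit definitions: topologies, kinetic parameters and reaction systems.

The circuit under study is a miRNA-controlled feed-forward loop (micFFL):
a miRNA represses both a transcription factor (TF) and a target gene (T)
that the TF transcriptionally activates.  The miRNA-mRNA interaction is
titrative: the two molecules form a complex which can only degrade (no
dissociation); with probability ``alpha`` the miRNA survives complex
degradation and is recycled.

Five null models are obtained by deleting interactions:

========  =========  ========  ========  =================
name      miRNA->TF  miRNA->T  TF->T     miRNA species
========  =========  ========  ========  =================
MICFFL    yes        yes       yes       one shared
NM1       no         no        yes       none
NM2       yes        no        yes       one
NM3       no         yes       yes       one
NM4       yes        yes       no        one shared
NM5       yes        yes       yes       two independent
========  =========  ========  ========  =================

All quantities are expressed in units rescaled by the target-protein
degradation rate (time unit = target-protein lifetime) once
:func:`rescale_parameters` has been applied.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = [
    "TopologyName",
    "CircuitTopology",
    "TOPOLOGIES",
    "get_topology",
    "KineticParameters",
    "hill_activation",
    "rescale_parameters",
    "unrescale_parameters",
    "Reaction",
    "ReactionSystem",
    "build_reaction_system",
    "interaction_strength",
    "kon_for_strength",
    "with_interaction_strength",
    "load_parameters",
    "save_parameters",
    # propensity kind codes (shared with the SSA kernel)
    "K_CONST",
    "K_LINEAR",
    "K_BIMOL",
    "K_HILL",
]


class TopologyName(str, enum.Enum):
    MICFFL = "MICFFL"
    NM1 = "NM1"
    NM2 = "NM2"
    NM3 = "NM3"
    NM4 = "NM4"
    NM5 = "NM5"


@dataclass(frozen=True)
class CircuitTopology:
    """Which interactions of the full micFFL are present.

    ``independent_mirnas`` means two distinct miRNA species with identical
    kinetics, one repressing the TF mRNA and one the target mRNA (NM5).
    """

    name: TopologyName
    mirna_targets_tf: bool
    mirna_targets_t: bool
    tf_regulates_t: bool
    independent_mirnas: bool = False

    def __post_init__(self) -> None:
        if self.independent_mirnas and not (
            self.mirna_targets_tf and self.mirna_targets_t
        ):
            raise ConfigurationError(
                "independent_mirnas requires both miRNA links to be present"
            )

    @property
    def has_mirna(self) -> bool:
        return self.mirna_targets_tf or self.mirna_targets_t

    @property
    def species(self) -> tuple[str, ...]:
        """Dynamical species of this topology, in canonical order."""
        out: list[str] = []
        if self.independent_mirnas:
            out += ["mi", "mi2"]
        elif self.has_mirna:
            out += ["mi"]
        out += ["mTF", "pTF", "mT", "pT"]
        if self.mirna_targets_tf:
            out.append("cTF")
        if self.mirna_targets_t:
            out.append("cT")
        return tuple(out)


TOPOLOGIES: dict[TopologyName, CircuitTopology] = {
    TopologyName.MICFFL: CircuitTopology(TopologyName.MICFFL, True, True, True),
    TopologyName.NM1: CircuitTopology(TopologyName.NM1, False, False, True),
    TopologyName.NM2: CircuitTopology(TopologyName.NM2, True, False, True),
    TopologyName.NM3: CircuitTopology(TopologyName.NM3, False, True, True),
    TopologyName.NM4: CircuitTopology(TopologyName.NM4, True, True, False),
    TopologyName.NM5: CircuitTopology(TopologyName.NM5, True, True, True, True),
}


def get_topology(name: str | TopologyName) -> CircuitTopology:
    return TOPOLOGIES[TopologyName(str(name).upper())]


_RATE_FIELDS = (
    # every per-time quantity; divided by g_pt on rescaling
    "k_mi", "g_mi",
    "k_mtf", "g_mtf", "k_ptf", "g_ptf",
    "k_mt", "g_mt", "k_pt", "g_pt",
    "k_on_tf", "k_on_t", "g_ctf", "g_ct",
)


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the titrative micFFL.

    Defaults are dimensionless (rescaled by the target-protein degradation
    rate, i.e. ``g_pt == 1``) and sit in the physiological band used
    throughout: mRNAs ~5x less stable than proteins, a handful of mRNA
    molecules and tens of protein molecules per cell at volume ``omega = 1``.

    Parameters
    ----------
    k_mi, g_mi : miRNA transcription (molecules/time) and degradation (1/time).
    k_mtf, g_mtf : TF mRNA transcription and degradation.
    k_ptf, g_ptf : TF translation (1/time per mRNA) and protein degradation.
    k_mt, g_mt : maximal target mRNA transcription (Hill numerator) and
        degradation.
    k_pt, g_pt : target translation and protein degradation (the rescaling
        unit; 1 in dimensionless form).
    k_on_tf, k_on_t : miRNA-mRNA complex formation rates (1/(molecule*time)).
    g_ctf, g_ct : complex degradation rates.
    alpha : probability that complex degradation recycles the miRNA.
    hill_n, hill_h : Hill coefficient and activation coefficient of the
        TF -> T transcriptional activation.
    basal : fraction of ``k_mt`` at which the target promoter transcribes
        when the TF->T link is absent (NM4).
    omega : system-size / volume scale; molecule counts are
        concentration * omega.
    """

    k_mi: float = 20.0
    g_mi: float = 1.0
    k_mtf: float = 20.0
    g_mtf: float = 5.0
    k_ptf: float = 5.0
    g_ptf: float = 1.0
    k_mt: float = 20.0
    g_mt: float = 5.0
    k_pt: float = 5.0
    g_pt: float = 1.0
    k_on_tf: float = 0.2
    k_on_t: float = 0.2
    g_ctf: float = 1.0
    g_ct: float = 1.0
    alpha: float = 0.0
    hill_n: float = 2.0
    hill_h: float = 1.0
    basal: float = 0.5
    omega: float = 1.0

    def __post_init__(self) -> None:
        for f in _RATE_FIELDS:
            v = getattr(self, f)
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"rate {f}={v!r} must be finite and >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha={self.alpha} outside [0, 1]")
        if not self.hill_h > 0:
            raise ConfigurationError(f"hill_h={self.hill_h} must be > 0")
        if not self.hill_n >= 1:
            raise ConfigurationError(f"hill_n={self.hill_n} must be >= 1")
        if not 0.0 <= self.basal <= 1.0:
            raise ConfigurationError(f"basal={self.basal} outside [0, 1]")
        if not self.omega > 0:
            raise ConfigurationError(f"omega={self.omega} must be > 0")

    def replace(self, **kwargs) -> "KineticParameters":
        return dataclasses.replace(self, **kwargs)

    def validate_for(self, topology: CircuitTopology) -> None:
        """Strict check that no rate is requested for an absent interaction."""
        if not topology.has_mirna and self.k_mi > 0:
            raise ConfigurationError(
                f"{topology.name.value} has no miRNA species but k_mi={self.k_mi} > 0"
            )
        if not topology.mirna_targets_tf and self.k_on_tf > 0:
            raise ConfigurationError(
                f"{topology.name.value} lacks the miRNA->TF link but k_on_tf > 0"
            )
        if not topology.mirna_targets_t and self.k_on_t > 0:
            raise ConfigurationError(
                f"{topology.name.value} lacks the miRNA->T link but k_on_t > 0"
            )


def hill_activation(ptf: float, n: float, h: float, k_max: float) -> float:
    """Activatory Hill function k_max * pTF^n / (pTF^n + h^n).

    Monotone increasing in ``ptf``, equal to ``k_max/2`` at ``ptf == h`` and
    saturating to ``k_max`` for ``ptf >> h``.
    """
    ptf_arr = np.asarray(ptf, dtype=float)
    if not np.all(np.isfinite(ptf_arr)) or np.any(ptf_arr < 0):
        raise ValueError(f"pTF must be finite and >= 0, got {ptf!r}")
    if not (math.isfinite(h) and h > 0):
        raise ValueError(f"h must be finite and > 0, got {h!r}")
    if not (math.isfinite(n) and n >= 1):
        raise ValueError(f"n must be finite and >= 1, got {n!r}")
    if not (math.isfinite(k_max) and k_max >= 0):
        raise ValueError(f"k_max must be finite and >= 0, got {k_max!r}")
    # (p/h)^n form avoids overflow for large p and large n
    with np.errstate(over="ignore"):
        x = (ptf_arr / h) ** n
    out = np.where(np.isinf(x), k_max, k_max * x / (1.0 + x))
    return out if out.ndim else float(out)


def hill_slope(ptf: float, n: float, h: float, k_max: float) -> float:
    """d/dpTF of :func:`hill_activation` (used by the LNA linearization)."""
    if ptf < 0:
        raise ValueError(f"pTF must be >= 0, got {ptf!r}")
    if ptf == 0.0:
        return 0.0 if n > 1 else k_max / h
    x = (ptf / h) ** n
    if np.isinf(x):
        return 0.0
    return k_max * n * x / (ptf * (1.0 + x) ** 2)


def rescale_parameters(params: KineticParameters) -> KineticParameters:
    """Return a dimensionless copy: every rate divided by the target-protein
    degradation rate (so ``g_pt == 1`` and time is measured in target-protein
    lifetimes).  Concentration-like quantities (``hill_h``, ``omega``) and
    pure numbers are untouched."""
    if params.g_pt <= 0:
        raise ZeroDivisionError("target-protein degradation rate must be > 0")
    scale = params.g_pt
    return params.replace(**{f: getattr(params, f) / scale for f in _RATE_FIELDS})


def unrescale_parameters(
    params: KineticParameters, target_protein_degradation: float
) -> KineticParameters:
    """Inverse of :func:`rescale_parameters` given the original ``g_pt``."""
    if target_protein_degradation <= 0:
        raise ZeroDivisionError("target-protein degradation rate must be > 0")
    s = target_protein_degradation
    return params.replace(**{f: getattr(params, f) * s for f in _RATE_FIELDS})


# ---------------------------------------------------------------------------
# Reaction system
# ---------------------------------------------------------------------------

# propensity kinds (integer codes shared with the numba SSA kernel)
K_CONST = 0   # a = c
K_LINEAR = 1  # a = c * x[i]
K_BIMOL = 2   # a = c * x[i] * x[j]
K_HILL = 3    # a = c * x[i]^n / (x[i]^n + h^n)


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: a stoichiometric change plus a propensity."""

    name: str
    changes: tuple[tuple[str, int], ...]  # (species, delta)
    kind: int
    rate: float                            # c above, already omega-scaled
    i: int = -1                            # species index (linear/bimol/hill)
    j: int = -1                            # second species index (bimol)
    hill_n: float = 0.0
    hill_h: float = 0.0                    # in count units (h * omega)

    def propensity(self, state: np.ndarray) -> float:
        if self.kind == K_CONST:
            return self.rate
        if self.kind == K_LINEAR:
            return self.rate * state[self.i]
        if self.kind == K_BIMOL:
            return self.rate * state[self.i] * state[self.j]
        x = float(state[self.i]) ** self.hill_n
        return self.rate * x / (x + self.hill_h ** self.hill_n)


class ReactionSystem:
    """Reaction list plus species bookkeeping for one topology.

    Counts live at volume ``omega``: propensities of zeroth-order reactions
    scale with omega, bimolecular rates with 1/omega, so concentrations
    (count/omega) are omega-invariant on average.
    """

    def __init__(
        self,
        topology: CircuitTopology,
        params: KineticParameters,
        reactions: Sequence[Reaction],
    ) -> None:
        self.topology = topology
        self.params = params
        self.reactions = list(reactions)
        self.species = topology.species
        self._index = {s: k for k, s in enumerate(self.species)}
        n_s, n_r = len(self.species), len(self.reactions)
        self.stoichiometry = np.zeros((n_r, n_s), dtype=np.int64)
        for r, rxn in enumerate(self.reactions):
            for sp, delta in rxn.changes:
                self.stoichiometry[r, self._index[sp]] += delta

    def index(self, species: str) -> int:
        return self._index[species]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def propensities(self, state: np.ndarray) -> np.ndarray:
        return np.array([r.propensity(state) for r in self.reactions], dtype=float)

    def drift(self, state: np.ndarray) -> np.ndarray:
        """Macroscopic rate of change S^T a(x); the deterministic ODE
        right-hand side in count units."""
        return self.stoichiometry.T @ self.propensities(state)

    def kernel_arrays(self):
        """Flat arrays describing the propensities, consumed by the SSA kernel."""
        n = self.n_reactions
        kind = np.zeros(n, dtype=np.int64)
        rate = np.zeros(n, dtype=np.float64)
        idx_i = np.zeros(n, dtype=np.int64)
        idx_j = np.zeros(n, dtype=np.int64)
        h_n = np.zeros(n, dtype=np.float64)
        h_h = np.zeros(n, dtype=np.float64)
        for r, rxn in enumerate(self.reactions):
            kind[r] = rxn.kind
            rate[r] = rxn.rate
            idx_i[r] = rxn.i
            idx_j[r] = rxn.j
            h_n[r] = rxn.hill_n
            h_h[r] = rxn.hill_h
        return kind, rate, idx_i, idx_j, h_n, h_h


def _complex_degradation(
    complex_sp: str, mirna_sp: str, g_c: float, alpha: float, c_idx: int
) -> list[Reaction]:
    """Complex degradation split into a recycling channel (the miRNA is
    returned intact, probability alpha) and a full-degradation channel."""
    out: list[Reaction] = []
    if alpha > 0.0:
        out.append(
            Reaction(
                f"recycle_{complex_sp}",
                ((complex_sp, -1), (mirna_sp, +1)),
                K_LINEAR,
                alpha * g_c,
                i=c_idx,
            )
        )
    if alpha < 1.0:
        out.append(
            Reaction(
                f"degrade_{complex_sp}",
                ((complex_sp, -1),),
                K_LINEAR,
                (1 - alpha) * g_c,
                i=c_idx,
            )
        )
    return out


def build_reaction_system(
    params: KineticParameters,
    topology: CircuitTopology | str,
    *,
    strict: bool = False,
) -> ReactionSystem:
    """Assemble the reaction channels of a topology.

    Transcription of the target mRNA uses the activatory Hill propensity when
    the TF->T link is present and the basal constant rate otherwise.  Each
    present miRNA->mRNA link contributes mass-action complex formation plus
    the alpha-branched complex degradation; complexes never dissociate.

    With ``strict=True`` a nonzero rate requested for an absent interaction
    raises :class:`ConfigurationError`; by default such rates are ignored.
    """
    if isinstance(topology, str):
        topology = get_topology(topology)
    if strict:
        params.validate_for(topology)
    p, om = params, params.omega
    species = topology.species
    idx = {s: k for k, s in enumerate(species)}
    rxns: list[Reaction] = []

    # miRNA transcription / degradation
    mirnas = [s for s in species if s.startswith("mi")]
    for m in mirnas:
        rxns.append(Reaction(f"transcribe_{m}", ((m, +1),), K_CONST, p.k_mi * om))
        rxns.append(Reaction(f"degrade_{m}", ((m, -1),), K_LINEAR, p.g_mi, i=idx[m]))

    # TF mRNA and protein
    rxns.append(Reaction("transcribe_mTF", (("mTF", +1),), K_CONST, p.k_mtf * om))
    rxns.append(Reaction("degrade_mTF", (("mTF", -1),), K_LINEAR, p.g_mtf, i=idx["mTF"]))
    rxns.append(Reaction("translate_pTF", (("pTF", +1),), K_LINEAR, p.k_ptf, i=idx["mTF"]))
    rxns.append(Reaction("degrade_pTF", (("pTF", -1),), K_LINEAR, p.g_ptf, i=idx["pTF"]))

    # target mRNA and protein
    if topology.tf_regulates_t:
        rxns.append(
            Reaction(
                "transcribe_mT",
                (("mT", +1),),
                K_HILL,
                p.k_mt * om,
                i=idx["pTF"],
                hill_n=p.hill_n,
                hill_h=p.hill_h * om,
            )
        )
    else:
        rxns.append(
            Reaction("transcribe_mT", (("mT", +1),), K_CONST, p.basal * p.k_mt * om)
        )
    rxns.append(Reaction("degrade_mT", (("mT", -1),), K_LINEAR, p.g_mt, i=idx["mT"]))
    rxns.append(Reaction("translate_pT", (("pT", +1),), K_LINEAR, p.k_pt, i=idx["mT"]))
    rxns.append(Reaction("degrade_pT", (("pT", -1),), K_LINEAR, p.g_pt, i=idx["pT"]))

    # titration channels
    if topology.mirna_targets_tf:
        m = "mi"
        rxns.append(
            Reaction(
                "bind_mi_mTF",
                ((m, -1), ("mTF", -1), ("cTF", +1)),
                K_BIMOL,
                p.k_on_tf / om,
                i=idx[m],
                j=idx["mTF"],
            )
        )
        rxns.extend(_complex_degradation("cTF", m, p.g_ctf, p.alpha, idx["cTF"]))
    if topology.mirna_targets_t:
        m = "mi2" if topology.independent_mirnas else "mi"
        rxns.append(
            Reaction(
                "bind_mi_mT",
                ((m, -1), ("mT", -1), ("cT", +1)),
                K_BIMOL,
                p.k_on_t / om,
                i=idx[m],
                j=idx["mT"],
            )
        )
        rxns.extend(_complex_degradation("cT", m, p.g_ct, p.alpha, idx["cT"]))

    return ReactionSystem(topology, params, rxns)


# ---------------------------------------------------------------------------
# Interaction strength
# ---------------------------------------------------------------------------

def interaction_strength(
    params: KineticParameters, channel: str = "t"
) -> float:
    """Dimensionless miRNA-mRNA interaction strength F = k_on / g_complex.

    ``channel`` selects the TF ("tf") or target ("t") titration channel.
    The compound is the sweep axis of the correlation heat maps; a different
    definition can be used by passing custom callables to the scan functions.
    """
    if channel == "t":
        return params.k_on_t / params.g_ct
    if channel == "tf":
        return params.k_on_tf / params.g_ctf
    raise ValueError(f"unknown channel {channel!r}")


def kon_for_strength(strength: float, g_complex: float) -> float:
    """Invert :func:`interaction_strength`: the k_on realizing strength F."""
    if strength < 0:
        raise ValueError("interaction strength must be >= 0")
    return strength * g_complex


def with_interaction_strength(
    params: KineticParameters,
    strength: float,
    *,
    invert: Callable[[float, float], float] = kon_for_strength,
) -> KineticParameters:
    """Copy of ``params`` with both titration channels set to strength F."""
    return params.replace(
        k_on_tf=invert(strength, params.g_ctf),
        k_on_t=invert(strength, params.g_ct),
    )


# ---------------------------------------------------------------------------
# YAML i/o
# ---------------------------------------------------------------------------

def load_parameters(path) -> tuple[KineticParameters, CircuitTopology]:
    """Read a YAML parameter file: one mapping per rate constant plus a
    ``topology:`` key naming one of the six circuit variants."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "topology" not in doc:
        raise ConfigurationError(f"{path}: missing 'topology' key")
    topology = get_topology(doc.pop("topology"))
    known = {f.name for f in dataclasses.fields(KineticParameters)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    params = KineticParameters(**{k: float(v) for k, v in doc.items()})
    return params, topology


def save_parameters(path, params: KineticParameters, topology: CircuitTopology) -> None:
    doc = dataclasses.asdict(params)
    doc["topology"] = topology.name.value
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
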