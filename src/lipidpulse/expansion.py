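"""Label-resolved expansion of the base network.

A label-aware model tracks, for every species with ``c`` acyl chains, the
multiset of chain labels it carries: each chain is either unlabeled (symbol
``u``, encoded 0) or carries one of the ``N_L`` medium labels (1..N_L).
Because chain positions are biochemically equivalent, only the multiset
matters, so a species with ``c`` chains expands into ``C(N_L + c, c)``
variants.  Rules expand into reaction instances over variants; the single
rate parameter of each rule is shared by all of its instances, and
deacylation instances carry fractional multiplicity weights (released-chain
multiplicity over total chains) so that every chain of the parent is equally
likely to be released.  Under this convention the label-blind aggregate of
the expanded dynamics reproduces the base-network dynamics exactly — the
formal statement of "reactions are agnostic to labeling".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
import scipy.sparse as sp

from .network import BaseNetwork, build_base_network

__all__ = [
    "LabelState",
    "enumerate_label_states",
    "ReactionInstance",
    "ExpandedSpecies",
    "ExpandedModel",
    "expand_network",
    "aggregate",
    "aggregation_matrix",
    "state_label",
]

#: A label state is the sorted tuple of per-chain label symbols (0 = unlabeled).
LabelState = tuple[int, ...]


def enumerate_label_states(c: int, n_labels: int) -> list[LabelState]:
    """All size-``c`` multisets over ``{u, 1, .., n_labels}``, lexicographic.

    The count is ``C(n_labels + c, c)`` (stars and bars).  The unlabeled
    symbol sorts first, so the all-unlabeled state is always index 0.
    """
    if c < 0 or n_labels < 0:
        raise ValueError(f"chain count and label count must be >= 0, got ({c}, {n_labels})")
    return list(itertools.combinations_with_replacement(range(n_labels + 1), c))


def state_label(state: LabelState) -> str:
    """Human-readable suffix for a label state, e.g. ``u_1_2``."""
    return "_".join("u" if s == 0 else str(s) for s in state)


@dataclass(frozen=True)
class ExpandedSpecies:
    """One label variant of a base species."""

    base_index: int
    base_name: str
    state: LabelState

    @property
    def id(self) -> str:
        if not self.state:
            return self.base_name
        return f"{self.base_name}__{state_label(self.state)}"

    def label_count(self, label: int) -> int:
        return self.state.count(label)


@dataclass(frozen=True)
class ReactionInstance:
    """One concrete reaction between label variants.

    ``multiplicity`` is exact (a :class:`fractions.Fraction` in (0, 1]);
    ``influx_label`` is the label symbol produced by an FA-influx instance
    (gated by the active medium phase) or ``None`` for ordinary instances.
    """

    rule_id: str
    param_index: int
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    multiplicity: Fraction = Fraction(1)
    influx_label: int | None = None


@dataclass(frozen=True)
class ExpandedModel:
    """Label-resolved mass-action reaction network."""

    base: BaseNetwork
    n_labels: int
    species: tuple[ExpandedSpecies, ...]
    instances: tuple[ReactionInstance, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {(s.base_name, s.state): i for i, s in enumerate(self.species)}
        )

    @property
    def n_x(self) -> int:
        return len(self.species)

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def n_parameters(self) -> int:
        return self.base.n_rules

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.base.parameter_names

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    def index_of(self, base_name: str, state: LabelState) -> int:
        return self._index[(base_name, tuple(sorted(state)))]

    # -- observables -----------------------------------------------------

    @property
    def observable_indices(self) -> np.ndarray:
        """Indices of every chain-carrying variant (the measured quantities)."""
        return np.array(
            [i for i, s in enumerate(self.species)
             if self.base.species[s.base_index].n_chains > 0],
            dtype=np.intp,
        )

    @property
    def observable_ids(self) -> tuple[str, ...]:
        return tuple(self.species[i].id for i in self.observable_indices)

    @property
    def n_observables(self) -> int:
        return int(self.observable_indices.size)

    # -- variant blocks --------------------------------------------------

    def variant_indices(self, base_name: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.species) if s.base_name == base_name],
            dtype=np.intp,
        )

    def unlabeled_index(self, base_name: str) -> int:
        c = self.base.species_by_name(base_name).n_chains
        return self._index[(base_name, (0,) * c)]


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------


def _chain_partners(base: BaseNetwork, names: tuple[str, ...]):
    chain = [n for n in names if base.species_by_name(n).n_chains > 0]
    plain = [n for n in names if base.species_by_name(n).n_chains == 0]
    return chain, plain


def expand_network(base: BaseNetwork | None = None, n_labels: int = 0) -> ExpandedModel:
    """Expand a base network into its label-resolved reaction network.

    Species are ordered by base-species position, then lexicographically by
    label state (unlabeled first); instances are ordered by rule, then by
    reactant variant, so serialization is deterministic.
    """
    if base is None:
        base = build_base_network()
    if n_labels < 0:
        raise ValueError(f"n_labels must be >= 0, got {n_labels}")

    species: list[ExpandedSpecies] = []
    for i, s in enumerate(base.species):
        for st in enumerate_label_states(s.n_chains, n_labels):
            species.append(ExpandedSpecies(i, s.name, st))
    index = {(s.base_name, s.state): i for i, s in enumerate(species)}

    def idx(name: str, state: LabelState) -> int:
        return index[(name, tuple(sorted(state)))]

    instances: list[ReactionInstance] = []
    for pi, rule in enumerate(base.rules):
        cls = rule.rule_class
        if cls == "headgroup":
            instances.append(
                ReactionInstance(
                    rule.id, pi,
                    tuple(idx(n, ()) for n in rule.reactants),
                    tuple(idx(n, ()) for n in rule.products),
                )
            )
        elif cls == "influx_FA":
            (product,) = rule.products
            for lbl in range(n_labels + 1):
                instances.append(
                    ReactionInstance(rule.id, pi, (), (idx(product, (lbl,)),),
                                     influx_label=lbl)
                )
        elif cls in ("unimolecular_1chain", "tag_unimolecular"):
            # chain-carrying efflux: every variant leaves the system
            (reactant,) = rule.reactants
            c = base.species_by_name(reactant).n_chains
            for st in enumerate_label_states(c, n_labels):
                instances.append(ReactionInstance(rule.id, pi, (idx(reactant, st),), ()))
        elif cls in ("acylation", "tag_acylation"):
            chain_r, plain_r = _chain_partners(base, rule.reactants)
            fa = next(n for n in chain_r if base.species_by_name(n).n_chains == 1)
            acceptors = [n for n in chain_r if n != fa]
            acceptor = acceptors[0] if acceptors else plain_r[0]
            (product,) = rule.products
            c_acc = base.species_by_name(acceptor).n_chains
            for st in enumerate_label_states(c_acc, n_labels):
                for (b,) in enumerate_label_states(1, n_labels):
                    instances.append(
                        ReactionInstance(
                            rule.id, pi,
                            (idx(acceptor, st), idx(fa, (b,))),
                            (idx(product, tuple(sorted(st + (b,)))),),
                        )
                    )
        elif cls in ("deacylation", "tag_deacylation"):
            (parent,) = rule.reactants
            c = base.species_by_name(parent).n_chains
            fa = next(
                n for n in rule.products if base.species_by_name(n).n_chains == 1
            )
            child = next(n for n in rule.products if n != fa)
            for st in enumerate_label_states(c, n_labels):
                for v in sorted(set(st)):
                    rest = list(st)
                    rest.remove(v)
                    instances.append(
                        ReactionInstance(
                            rule.id, pi,
                            (idx(parent, st),),
                            (idx(child, tuple(rest)), idx(fa, (v,))),
                            multiplicity=Fraction(st.count(v), c),
                        )
                    )
        elif cls == "transfer":
            chain_r, plain_r = _chain_partners(base, rule.reactants)
            chain_p, plain_p = _chain_partners(base, rule.products)
            if len(chain_r) != 1 or len(chain_p) != 1:
                raise ValueError(
                    f"transfer rule {rule.id!r} needs exactly one chain-carrying "
                    "reactant and product"
                )
            src, dst = chain_r[0], chain_p[0]
            c = base.species_by_name(src).n_chains
            if base.species_by_name(dst).n_chains != c:
                raise ValueError(f"transfer rule {rule.id!r} must preserve chain count")
            for st in enumerate_label_states(c, n_labels):
                instances.append(
                    ReactionInstance(
                        rule.id, pi,
                        (idx(src, st), *(idx(n, ()) for n in plain_r)),
                        (idx(dst, st), *(idx(n, ()) for n in plain_p)),
                    )
                )
        else:  # pragma: no cover - guarded by ReactionRule validation
            raise ValueError(f"rule {rule.id!r}: unsupported rule class {cls!r}")

    return ExpandedModel(base, n_labels, tuple(species), tuple(instances))


def expected_counts(base: BaseNetwork, n_labels: int) -> tuple[int, int]:
    """Closed-form (species, instance) counts of the expansion.

    Species: sum of ``C(N_L + c, c)`` over base species.  Instances: per rule
    class, the number of distinct (reactant-variant, assignment) choices.
    Used as an independent cross-check of :func:`expand_network`.
    """
    v = [comb(n_labels + c, c) for c in range(4)]
    n_species = sum(v[s.n_chains] for s in base.species)
    n_inst = 0
    for rule in base.rules:
        cls = rule.rule_class
        if cls == "headgroup":
            n_inst += 1
        elif cls == "influx_FA":
            n_inst += v[1]
        elif cls in ("unimolecular_1chain", "tag_unimolecular", "transfer"):
            chain = [n for n in rule.reactants if base.species_by_name(n).n_chains > 0]
            c = base.species_by_name(chain[0]).n_chains if chain else 0
            n_inst += v[c]
        elif cls in ("acylation", "tag_acylation"):
            fa_free = [
                base.species_by_name(n).n_chains
                for n in rule.reactants
            ]
            c_acc = sum(fa_free) - 1
            n_inst += v[c_acc] * v[1]
        elif cls in ("deacylation", "tag_deacylation"):
            (parent,) = rule.reactants
            c = base.species_by_name(parent).n_chains
            # one instance per (remaining multiset, released label) pair
            n_inst += v[c - 1] * v[1]
    return n_species, n_inst


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregation_matrix(model: ExpandedModel) -> sp.csr_matrix:
    """Sparse 0/1 matrix mapping expanded states to per-base-species totals."""
    rows = [s.base_index for s in model.species]
    cols = list(range(model.n_x))
    data = np.ones(model.n_x)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(model.base.n_species, model.n_x)
    )


def aggregate(model: ExpandedModel, x: np.ndarray) -> np.ndarray:
    """Per-base-species totals (sums over label variants) of a state vector.

    Accepts a vector of length ``n_x`` or an array whose last axis has
    length ``n_x``.
    """
    x = np.asarray(x)
    if x.shape[-1] != model.n_x:
        raise ValueError(f"state vector has length {x.shape[-1]}, expected {model.n_x}")
    out = np.zeros(x.shape[:-1] + (model.base.n_species,))
    for i, s in enumerate(model.species):
        out[..., s.base_index] += x[..., i]
    return out


def permute_labels(state: LabelState, perm: dict[int, int]) -> LabelState:
    """Apply a permutation of label symbols (0 stays fixed) to a state."""
    return tuple(sorted(perm.get(s, s) for s in state))
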