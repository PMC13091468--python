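"""Label-free base network of fatty-acid / glycerolipid / phospholipid metabolism.

The base network is the rule level of the model: 22 metabolite pools and 40
irreversible mass-action reaction rules covering triacylglycerol synthesis and
lipolysis (GLY, G3P, LPA, PA, MAG, DAG, TAG) and the phosphatidyl-choline /
-ethanolamine / -serine branches of phospholipid metabolism, with lumped
in-/out-fluxes.  ATP and acyl-CoA are held constant and folded into the rate
constants, so free fatty acid (FA) appears directly in the acyl-transfer
steps; beta-oxidation is lumped into a single FA efflux.

Each species carries ``n_chains`` esterifiable acyl positions (0 for head
groups, 1 for FA/lyso-species/MAG, 2 for diacyl species, 3 for TAG); the
label-resolved expansion in :mod:`lipidpulse.expansion` enumerates multisets
of chain labels per species.  Each rule owns exactly one rate parameter
``k<i>``, and labels never alter a rate: labeled and unlabeled molecules are
biochemically identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "BaseSpecies",
    "ReactionRule",
    "BaseNetwork",
    "RULE_CLASSES",
    "build_base_network",
    "read_network",
    "write_network",
]

#: Reaction-rule classes.  The class determines how the rule is instantiated
#: over label multisets during expansion:
#:
#: - ``headgroup``: only 0-chain species participate; one instance.
#: - ``influx_FA``: label-switched FA source; one instance per label symbol,
#:   gated by the active medium phase.
#: - ``unimolecular_1chain``: a 1-chain species leaves the system (chains exit).
#: - ``acylation`` / ``tag_acylation``: an FA chain is esterified onto an
#:   acceptor; label multisets merge.
#: - ``deacylation`` / ``tag_deacylation``: one chain is released as FA; one
#:   instance per distinct release choice, weighted by chain multiplicity.
#: - ``transfer``: the chain multiset passes unchanged between two species.
#: - ``tag_unimolecular``: TAG efflux (chains exit).
RULE_CLASSES = frozenset(
    {
        "headgroup",
        "influx_FA",
        "unimolecular_1chain",
        "acylation",
        "deacylation",
        "transfer",
        "tag_unimolecular",
        "tag_acylation",
        "tag_deacylation",
    }
)

#: Classes whose instances remove acyl chains from the system.
EFFLUX_CLASSES = frozenset({"unimolecular_1chain", "tag_unimolecular"})


@dataclass(frozen=True)
class BaseSpecies:
    """A metabolite pool with a fixed number of esterifiable acyl positions."""

    name: str
    n_chains: int

    def __post_init__(self) -> None:
        if self.n_chains not in (0, 1, 2, 3):
            raise ValueError(
                f"species {self.name!r}: n_chains must be in 0..3, got {self.n_chains}"
            )


@dataclass(frozen=True)
class ReactionRule:
    """One irreversible mass-action rule with a single rate parameter.

    ``reactants``/``products`` are tuples of species names (0, 1 or 2
    reactants; up to 2 products).  The rate parameter symbol is ``k<index>``
    where the index is the 1-based position of the rule in the network.
    """

    id: str
    rule_class: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.rule_class not in RULE_CLASSES:
            raise ValueError(f"rule {self.id!r}: unknown rule class {self.rule_class!r}")
        if len(self.reactants) > 2:
            raise ValueError(f"rule {self.id!r}: at most 2 reactants supported")


@dataclass(frozen=True)
class BaseNetwork:
    """Validated collection of species and reaction rules."""

    species: tuple[BaseSpecies, ...]
    rules: tuple[ReactionRule, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("rule ids must be unique")
        object.__setattr__(self, "_index", {s.name: s for s in self.species})
        for rule in self.rules:
            for name in (*rule.reactants, *rule.products):
                if name not in self._index:
                    raise ValueError(f"rule {rule.id!r} references unknown species {name!r}")
            self._audit_chains(rule)

    # -- queries ---------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        """Rate-parameter symbols ``k1..k<n_rules>`` in rule order."""
        return tuple(f"k{i + 1}" for i in range(len(self.rules)))

    def species_by_name(self, name: str) -> BaseSpecies:
        return self._index[name]

    def chains(self, names: Iterable[str]) -> int:
        return sum(self._index[n].n_chains for n in names)

    # -- validation ------------------------------------------------------

    def _audit_chains(self, rule: ReactionRule) -> None:
        """Acyl chains are conserved except where a rule exports them."""
        chains_in = self.chains(rule.reactants)
        chains_out = self.chains(rule.products)
        if rule.rule_class == "influx_FA":
            chains_in += 1
        if rule.rule_class in EFFLUX_CLASSES:
            if rule.products:
                raise ValueError(f"efflux rule {rule.id!r} must have no products")
            return
        if chains_in != chains_out:
            raise ValueError(
                f"rule {rule.id!r} violates chain conservation: "
                f"{chains_in} chains in, {chains_out} out"
            )


# ---------------------------------------------------------------------------
# Pinned default network
# ---------------------------------------------------------------------------

_PINNED_SPECIES: tuple[tuple[str, int], ...] = (
    ("GLY", 0), ("G3P", 0), ("Cho", 0), ("ChoP", 0), ("CDPCho", 0),
    ("Etn", 0), ("EtnP", 0), ("CDPEtn", 0), ("Ser", 0), ("GPC", 0),
    ("GPE", 0),
    ("FA", 1), ("LPA", 1), ("MAG", 1), ("LPC", 1), ("LPE", 1),
    ("PA", 2), ("DAG", 2), ("PC", 2), ("PE", 2), ("PS", 2),
    ("TAG", 3),
)

# (id, class, reactants, products)
_PINNED_RULES: tuple[tuple[str, str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("R1", "headgroup", (), ("G3P",)),
    ("R2", "headgroup", (), ("GLY",)),
    ("R3", "headgroup", ("GLY",), ("G3P",)),
    ("R4", "headgroup", ("GLY",), ()),
    ("R5", "headgroup", ("G3P",), ()),
    ("R6", "headgroup", (), ("Cho",)),
    ("R7", "headgroup", ("Cho",), ()),
    ("R8", "headgroup", ("Cho",), ("ChoP",)),
    ("R9", "headgroup", ("ChoP",), ("Cho",)),
    ("R10", "headgroup", ("ChoP",), ("CDPCho",)),
    ("R11", "headgroup", ("CDPCho",), ("ChoP",)),
    ("R12", "headgroup", ("GPC",), ("Cho", "G3P")),
    ("R13", "headgroup", (), ("Etn",)),
    ("R14", "headgroup", ("Etn",), ()),
    ("R15", "headgroup", ("Etn",), ("EtnP",)),
    ("R16", "headgroup", ("EtnP",), ("Etn",)),
    ("R17", "headgroup", ("EtnP",), ("CDPEtn",)),
    ("R18", "headgroup", ("CDPEtn",), ("EtnP",)),
    ("R19", "headgroup", ("GPE",), ("Etn", "G3P")),
    ("R20", "headgroup", (), ("Ser",)),
    ("R21", "headgroup", ("Ser",), ()),
    ("R22", "influx_FA", (), ("FA",)),
    ("R23", "unimolecular_1chain", ("FA",), ()),
    ("R24", "acylation", ("G3P", "FA"), ("LPA",)),
    ("R25", "deacylation", ("LPA",), ("G3P", "FA")),
    ("R26", "deacylation", ("MAG",), ("GLY", "FA")),
    ("R27", "deacylation", ("LPC",), ("GPC", "FA")),
    ("R28", "deacylation", ("LPE",), ("GPE", "FA")),
    ("R29", "transfer", ("PA",), ("DAG",)),
    ("R30", "transfer", ("CDPCho", "DAG"), ("PC",)),
    ("R31", "transfer", ("CDPEtn", "DAG"), ("PE",)),
    ("R32", "transfer", ("PE", "Ser"), ("PS", "Etn")),
    ("R33", "transfer", ("PS",), ("PE",)),
    ("R34", "acylation", ("LPA", "FA"), ("PA",)),
    ("R35", "deacylation", ("DAG",), ("MAG", "FA")),
    ("R36", "deacylation", ("PC",), ("LPC", "FA")),
    ("R37", "deacylation", ("PE",), ("LPE", "FA")),
    ("R38", "tag_unimolecular", ("TAG",), ()),
    ("R39", "tag_acylation", ("DAG", "FA"), ("TAG",)),
    ("R40", "tag_deacylation", ("TAG",), ("DAG", "FA")),
)


def build_base_network() -> BaseNetwork:
    """Return the pinned 22-species / 40-rule lipid metabolism network."""
    species = tuple(BaseSpecies(n, c) for n, c in _PINNED_SPECIES)
    rules = tuple(ReactionRule(i, cls, r, p) for i, cls, r, p in _PINNED_RULES)
    return BaseNetwork(species, rules)


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------
#
# Format (tab-separated, UTF-8):
#   species <TAB> <name> <TAB> <n_chains>
#   rule <TAB> <id> <TAB> <class> <TAB> <A + B or -> <TAB> <C + D or ->


def write_network(network: BaseNetwork, path: str | Path) -> None:
    lines = ["# lipidpulse base network"]
    for s in network.species:
        lines.append(f"species\t{s.name}\t{s.n_chains}")
    for r in network.rules:
        lhs = " + ".join(r.reactants) or "-"
        rhs = " + ".join(r.products) or "-"
        lines.append(f"rule\t{r.id}\t{r.rule_class}\t{lhs}\t{rhs}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_side(text: str) -> tuple[str, ...]:
    text = text.strip()
    if text in ("-", ""):
        return ()
    return tuple(part.strip() for part in text.split("+"))


def read_network(path: str | Path) -> BaseNetwork:
    species: list[BaseSpecies] = []
    rules: list[ReactionRule] = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        kind = fields[0]
        try:
            if kind == "species":
                species.append(BaseSpecies(fields[1], int(fields[2])))
            elif kind == "rule":
                rules.append(
                    ReactionRule(fields[1], fields[2], _parse_side(fields[3]), _parse_side(fields[4]))
                )
            else:
                raise ValueError(f"unknown record kind {kind!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return BaseNetwork(tuple(species), tuple(rules))


def load_network(source: str | Path) -> BaseNetwork:
    """Load a network from a file path, or the pinned default for ``"pinned"``."""
    if str(source) == "pinned":
        return build_base_network()
    return read_network(source)
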