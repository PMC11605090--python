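"""Enumeration of the constrained candidate space for positional isomers.

The search space deliberately covers only double-bond and hydroxyl positions
known in lipid biology (mammal-biased defaults): a curated per-chain-length
table of monounsaturated positions, the omega-3/6/9 rule, methylene-
interrupted n-3/n-6/n-9 series for polyunsaturated chains, and the
delta-4/8/14 set for sphingoid bases (delta 6 excluded; a single sphingoid
double bond is fixed at delta 4).  The tool ranks candidates within this
space; it is not meant to discover new positions.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .chains import AcylChain, ChainKind
from .lipids import SUBCLASSES, LipidStructure

logger = logging.getLogger(__name__)

#: Curated monounsaturated double-bond (delta) positions per chain length,
#: reconstructed from positions common in mammalian lipid databases.
#: User-overridable through :class:`CandidateConfig`.
CURATED_MUFA_POSITIONS: dict[int, tuple[int, ...]] = {
    14: (9,),
    16: (7, 9, 11),
    17: (9, 10),
    18: (9, 11, 13),
    19: (9, 10),
    20: (9, 11, 13),
    22: (11, 13),
    24: (15, 17),
    26: (17,),
}

#: Sphingoid-base candidate positions (delta 6 excluded as unusual in mammals).
SPHINGOID_DB_POSITIONS: tuple[int, ...] = (4, 8, 14)

#: PUFA families: terminal methyl offset (omega number) of the last double bond.
PUFA_FAMILIES: tuple[int, ...] = (3, 6, 9)


@dataclass(frozen=True)
class CandidateConfig:
    """Tunable definition of the candidate chemical space."""

    mufa_positions: dict[int, tuple[int, ...]] = field(
        default_factory=lambda: dict(CURATED_MUFA_POSITIONS)
    )
    omega_offsets: tuple[int, ...] = (3, 6, 9)
    pufa_families: tuple[int, ...] = PUFA_FAMILIES
    sphingoid_positions: tuple[int, ...] = SPHINGOID_DB_POSITIONS
    max_candidates: int = 10_000
    min_chain_carbons: int = 10       # for species-level chain splitting
    max_chain_carbons: int = 38

    @classmethod
    def from_yaml(cls, path: str) -> "CandidateConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls._from_mapping(raw)

    @classmethod
    def from_toml(cls, path: str) -> "CandidateConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "CandidateConfig":
        kwargs = {}
        if "mufa_positions" in raw:
            kwargs["mufa_positions"] = {
                int(k): tuple(v) for k, v in raw["mufa_positions"].items()
            }
        for key in ("omega_offsets", "pufa_families", "sphingoid_positions"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("max_candidates", "min_chain_carbons", "max_chain_carbons"):
            if key in raw:
                kwargs[key] = int(raw[key])
        return cls(**kwargs)


DEFAULT_CONFIG = CandidateConfig()


def mufa_positions(
    chain_carbons: int, config: CandidateConfig = DEFAULT_CONFIG
) -> list[int]:
    """Candidate delta positions for a single double bond.

    Union of the curated database-listed positions for that chain length and
    the omega-3/6/9 positions (delta = carbons - offset), deduplicated and
    ascending.
    """
    if chain_carbons < 4:
        return []
    out = set(config.mufa_positions.get(chain_carbons, ()))
    for off in config.omega_offsets:
        delta = chain_carbons - off
        if 2 <= delta <= chain_carbons - 1:
            out.add(delta)
    return sorted(out)


def pufa_series(
    chain_carbons: int,
    double_bonds: int,
    config: CandidateConfig = DEFAULT_CONFIG,
) -> list[tuple[int, ...]]:
    """Methylene-interrupted position runs for the n-3/6/9 families.

    Each family is an arithmetic sequence with step 3 whose last position
    sits ``family`` carbons from the terminal methyl (delta = carbons -
    family); families that do not fit inside the chain are omitted.
    """
    if double_bonds < 2:
        raise ValueError("pufa_series needs at least two double bonds")
    out = []
    for fam in config.pufa_families:
        last = chain_carbons - fam
        first = last - 3 * (double_bonds - 1)
        if first >= 2 and last <= chain_carbons - 1:
            out.append(tuple(range(first, last + 1, 3)))
    return out


def sphingoid_positions(
    double_bonds: int, config: CandidateConfig = DEFAULT_CONFIG
) -> list[tuple[int, ...]]:
    """Candidate double-bond position sets for a sphingoid base.

    One double bond is fixed at delta 4; more draw subsets of the candidate
    set (default {4, 8, 14}).
    """
    if double_bonds == 0:
        return [()]
    if double_bonds == 1:
        return [(4,)]
    pool = config.sphingoid_positions
    if double_bonds > len(pool):
        warnings.warn(
            f"no sphingoid candidates for {double_bonds} double bonds",
            stacklevel=2,
        )
        return []
    return [tuple(c) for c in itertools.combinations(sorted(pool), double_bonds)]


def _oh_position_candidates(chain: AcylChain) -> list[tuple[int, ...]]:
    """Hydroxyl-position candidates per chain.

    Sphingoid bases use the canonical head-adjacent pattern (1,3 / 1,3,4);
    acyl chains place hydroxyls alpha-first (2, 3, ...).
    """
    h = chain.hydroxyls
    if h == 0:
        return [()]
    if chain.oh_positions is not None:
        return [chain.oh_positions]
    if chain.kind is ChainKind.SPHINGOID:
        canonical = {1: (1,), 2: (1, 3), 3: (1, 3, 4)}
        if h in canonical:
            return [canonical[h]]
        return [tuple(range(1, h + 1))]
    return [tuple(range(2, h + 2))]


def _chain_db_candidates(
    chain: AcylChain, config: CandidateConfig
) -> list[tuple[int, ...]]:
    if chain.db_positions is not None:
        return [chain.db_positions]
    d = chain.double_bonds
    if d == 0:
        return [()]
    if chain.kind is ChainKind.SPHINGOID:
        return sphingoid_positions(d, config)
    if d == 1:
        return [(p,) for p in mufa_positions(chain.carbons, config)]
    return pufa_series(chain.carbons, d, config)


def _chain_provenance(chain: AcylChain, positions: tuple[int, ...],
                      config: CandidateConfig) -> str:
    if chain.double_bonds == 0 or not positions:
        return "saturated"
    if chain.kind is ChainKind.SPHINGOID:
        return "sphingoid"
    if chain.double_bonds == 1:
        if positions[0] in config.mufa_positions.get(chain.carbons, ()):
            return "curated"
        return "omega-rule"
    return "pufa-series"


_PROVENANCE_ORDER = {
    "curated": 0, "sphingoid": 0, "saturated": 0, "pufa-series": 1, "omega-rule": 2,
}


@dataclass(frozen=True)
class Candidate:
    structure: LipidStructure
    provenance: str  # worst provenance over chains


@dataclass
class CandidateSet:
    query: LipidStructure
    candidates: list[Candidate]
    truncated: bool = False

    @property
    def structures(self) -> list[LipidStructure]:
        return [c.structure for c in self.candidates]

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


def _sn_arrangements(query: LipidStructure) -> list[tuple[Optional[AcylChain], ...]]:
    """Distinct slot assignments of the query's chains."""
    info = query.info
    if query.sn_assigned:
        return [query.chains]
    chains = query.present_chains
    if info.category == "SP":
        return [chains]
    if info.lyso and len(chains) == 1:
        # sn1- and sn2-lyso arrangements
        return [(chains[0], None), (None, chains[0])]
    seen, out = set(), []
    for perm in itertools.permutations(chains):
        key = tuple(c.format() for c in perm)
        if key not in seen:
            seen.add(key)
            out.append(perm)
    return out


def _split_species(query: LipidStructure, config: CandidateConfig
                   ) -> list[LipidStructure]:
    """Molecular-species hypotheses for a species-level query."""
    info = query.info
    c_tot, d_tot, h_tot = query.species_totals
    n = info.n_chains
    if n == 1:
        chain = AcylChain(c_tot, d_tot, hydroxyls=h_tot)
        return [LipidStructure(query.subclass, (chain,))]
    if n != 2:
        return []  # three-chain splitting is out of the decision tree's scope
    out = []
    lo, hi = config.min_chain_carbons, config.max_chain_carbons
    for c1 in range(lo, min(hi, c_tot - lo) + 1):
        c2 = c_tot - c1
        if c2 < c1 or c2 > hi:
            continue
        for d1 in range(d_tot + 1):
            d2 = d_tot - d1
            if d1 > (c1 - 2) // 2 or d2 > (c2 - 2) // 2:
                continue
            if info.category == "SP":
                ch = (
                    AcylChain(c1, d1, ChainKind.SPHINGOID, hydroxyls=h_tot),
                    AcylChain(c2, d2, ChainKind.NACYL),
                )
                out.append(LipidStructure(query.subclass, ch, sn_assigned=True))
            else:
                ch = (AcylChain(c1, d1), AcylChain(c2, d2))
                out.append(LipidStructure(query.subclass, ch))
    return out


def enumerate_candidates(
    query: LipidStructure, config: CandidateConfig = DEFAULT_CONFIG
) -> CandidateSet:
    """Expand a species/molecular-species query into resolved candidates.

    Cartesian product of sn arrangements x per-chain double-bond position
    choices x hydroxyl position choices, deduplicated, deterministically
    ordered (curated positions before omega-rule fallbacks, then ascending
    positions, then slot order) and capped at ``config.max_candidates``.
    """
    queries = (
        _split_species(query, config) if query.is_species_level else [query]
    )
    raw: list[tuple[tuple, Candidate]] = []
    truncated = False
    seen = set()
    for q in queries:
        for slots in _sn_arrangements(q):
            per_chain: list[list[tuple[AcylChain, str]]] = []
            for chain in slots:
                if chain is None:
                    per_chain.append([(None, "saturated")])
                    continue
                opts = []
                for dbp in _chain_db_candidates(chain, config):
                    for ohp in _oh_position_candidates(chain):
                        resolved = replace(
                            chain,
                            db_positions=dbp if chain.double_bonds else None,
                            oh_positions=ohp if chain.hydroxyls else None,
                        )
                        opts.append(
                            (resolved, _chain_provenance(chain, dbp, config))
                        )
                per_chain.append(opts)
            for combo in itertools.product(*per_chain):
                chains = tuple(c for c, _ in combo)
                prov = max(
                    (p for _, p in combo), key=lambda p: _PROVENANCE_ORDER[p]
                )
                cand = LipidStructure(q.subclass, chains, sn_assigned=True)
                name = cand.format()
                if name in seen:
                    continue
                seen.add(name)
                sort_key = (
                    _PROVENANCE_ORDER[prov],
                    tuple(
                        (c.db_positions or ()) if c else ()
                        for c in chains
                    ),
                    name,
                )
                raw.append((sort_key, Candidate(cand, prov)))
                if len(raw) >= config.max_candidates:
                    truncated = True
                    logger.warning(
                        "candidate cap %d reached for %s; truncating",
                        config.max_candidates, query.format(),
                    )
                    break
            if truncated:
                break
        if truncated:
            break
    raw.sort(key=lambda t: t[0])
    return CandidateSet(query, [c for _, c in raw], truncated)
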