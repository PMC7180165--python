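"""Shared fixtures and independent oracle helpers.

The oracles here deliberately re-derive everything with naive pure-Python
loops (or a third-party route) so they share no code with the package's
vectorised implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from taxgap import (
    BarcodeSimConfig,
    GenotypeMatrix,
    GenotypeSimConfig,
    Site,
)

# --------------------------------------------------------------------------
# naive barcode oracles
# --------------------------------------------------------------------------

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def naive_counts(a: str, b: str) -> tuple[int, int, int]:
    """(n, ts, tv) by character-by-character inspection."""
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in PURINES and y in PURINES) or (
            x in PYRIMIDINES and y in PYRIMIDINES
        )
        if same_class:
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def naive_k2p(a: str, b: str) -> float | None:
    n, ts, tv = naive_counts(a, b)
    if n == 0:
        raise ZeroDivisionError
    p, q = ts / n, tv / n
    if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
        return None
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def naive_species_summaries(seqs: dict[str, str], species: dict[str, str]):
    """Brute-force per-species (n, mean_intra, max_intra) and NN analysis
    over all pairs, plus the full pairwise distance dict."""
    dist: dict[tuple[str, str], float | None] = {}
    for a, b in itertools.combinations(sorted(seqs), 2):
        dist[(a, b)] = dist[(b, a)] = naive_k2p(seqs[a], seqs[b])
    by_species: dict[str, list[str]] = {}
    for s, sp in species.items():
        by_species.setdefault(sp, []).append(s)
    intra = {}
    for sp, members in by_species.items():
        vals = [
            dist[(a, b)]
            for a, b in itertools.combinations(sorted(members), 2)
            if dist[(a, b)] is not None
        ]
        intra[sp] = (
            len(members),
            sum(vals) / len(vals) if vals else None,
            max(vals) if vals else None,
        )
    nn = {}
    for sp, members in by_species.items():
        best_d, best_sp = math.inf, None
        for other in sorted(by_species):
            if other == sp:
                continue
            for a in members:
                for b in by_species[other]:
                    d = dist[(a, b)]
                    if d is not None and d < best_d:
                        best_d, best_sp = d, other
        nn[sp] = (best_sp, best_d if best_sp else None)
    return dist, intra, nn


def naive_single_linkage(ids, dist, threshold):
    """Connected components via networkx — an independent graph route."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(ids)
    for (a, b), d in dist.items():
        if d is not None and d < threshold:
            g.add_edge(a, b)
    return {frozenset(c) for c in nx.connected_components(g)}


def related_alignment(rng: np.random.Generator, n_seqs: int, length: int = 60):
    """Random sequences mutated from a shared base so pairwise distances
    stay inside the K2P domain; sprinkles a few N/- symbols."""
    base = "".join(rng.choice(list("ACGT"), size=length))
    seqs = {}
    species = {}
    n_species = int(rng.integers(2, 4))
    for i in range(n_seqs):
        chars = list(base)
        for pos in rng.choice(length, size=int(rng.integers(0, 6)), replace=False):
            chars[pos] = "ACGT"[int(rng.integers(4))]
        for pos in rng.choice(length, size=int(rng.integers(0, 3)), replace=False):
            chars[pos] = "N" if rng.random() < 0.5 else "-"
        sid = f"s{i:02d}"
        seqs[sid] = "".join(chars)
        species[sid] = f"sp{int(rng.integers(n_species))}"
    # brute-force NN needs >= 2 species actually present
    labels = set(species.values())
    if len(labels) < 2:
        species[f"s{n_seqs - 1:02d}"] = "sp_extra"
    return seqs, species


# --------------------------------------------------------------------------
# naive genotype oracles
# --------------------------------------------------------------------------


def random_genotype_matrix(rng: np.random.Generator, n_samples=5, n_tags=10):
    """Random small matrix exercising missing, het and tri-allelic calls."""
    samples = [f"s{i}" for i in range(n_samples)]
    sites = []
    for t in range(n_tags):
        tag = f"t{t:02d}"
        for pos in range(int(rng.integers(1, 4))):
            alleles = list(rng.choice(list("ACGT"), size=int(rng.integers(1, 4)), replace=False))
            gts = []
            for _ in range(n_samples):
                if rng.random() < 0.15:
                    gts.append(None)
                else:
                    pair = rng.choice(alleles, size=2)
                    gts.append(tuple(sorted(pair)))
            sites.append(Site(tag, pos, tuple(gts)))
    return GenotypeMatrix(samples, sites)


def brute_force_fixed_sites(gm: GenotypeMatrix, groups: dict[str, str]):
    """Scan every site of every tag directly against the three stated
    conditions: tag complete, tag single-bi-allelic, allele sets disjoint."""
    labels = sorted(set(groups.values()))
    g1 = [i for i, s in enumerate(gm.samples) if groups[s] == labels[0]]
    g2 = [i for i, s in enumerate(gm.samples) if groups[s] == labels[1]]
    by_tag: dict[str, list[Site]] = {}
    for s in gm.sites:
        by_tag.setdefault(s.tag, []).append(s)
    out = set()
    for tag, sites in by_tag.items():
        if any(g is None for s in sites for g in s.genotypes):
            continue
        variable = [s for s in sites if len(s.observed_alleles) >= 2]
        if len(variable) != 1 or len(variable[0].observed_alleles) != 2:
            continue
        site = variable[0]
        a1 = {a for i in g1 for a in site.genotypes[i]}
        a2 = {a for i in g2 for a in site.genotypes[i]}
        if a1 and a2 and not (a1 & a2):
            out.add((site.tag, site.pos))
    return out


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------


@pytest.fixture
def two_species_sim():
    cfg = BarcodeSimConfig(
        n_species=2, per_species_n=(10, 10), d_intra=0.002, d_inter=0.04, seed=11
    )
    from taxgap import simulate_barcode_dataset

    return cfg, *simulate_barcode_dataset(cfg)


@pytest.fixture
def planted_sim():
    cfg = GenotypeSimConfig(
        group_sizes=(8, 5), n_tags=66, n_planted_fixed=30, seed=11
    )
    from taxgap import simulate_genotype_matrix

    return cfg, *simulate_genotype_matrix(cfg)
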