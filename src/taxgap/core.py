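"""Molecular species delimitation from barcodes and RADseq genotypes.

Two pipelines, plus the simulator that gives both of them ground truth:

* **Barcode-gap analysis.** Pairwise Kimura 2-parameter (K2P) and
  p-distances over an aligned COI matrix with pairwise deletion,
  per-species intraspecific summaries, nearest-neighbour (NN) species
  distances, an overall NN summary, and single-linkage threshold
  clustering as a transparent stand-in for BIN assignment.

* **Diagnostic-SNP discovery.** From a samples x sites genotype matrix
  grouped into ddRAD tags: keep loci genotyped in every sample (0%
  missing data), keep tags carrying exactly one bi-allelic SNP, count
  SNPs and parsimony-informative sites (PIS), and report the sites whose
  allele sets are disjoint between two species groups — fixed allelic
  differences, i.e. candidate species-diagnostic SNPs — together with
  per-sample observed heterozygosity.

* **Synthetic data.** Sequences evolved under the K2P substitution
  process on a star genealogy, and genotype matrices with a planted,
  bookkept number of fixed differences, so every downstream statistic
  can be checked against known truth.

Distances are held as substitutions/site (proportions) internally and
converted to percent only in reports. Genotypes are unordered allele
pairs over {A,C,G,T}, or missing. Sites are 0-based internally; every
external format (VCF, TSV reports) is 1-based.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter, OrderedDict
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__version__ = "0.1.0"

logger = logging.getLogger("taxgap")

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class TaxgapError(Exception):
    """Base class for all errors raised by this package."""


class InputError(TaxgapError):
    """Bad user input: unmapped samples, malformed files, empty data."""


class InvalidParameterError(InputError):
    """A parameter outside its mathematical or configured domain."""


class AlignmentError(InputError):
    """Sequences that cannot be compared (e.g. unequal lengths)."""


class NoOverlapError(TaxgapError):
    """A sequence pair with zero compared sites after pairwise deletion.

    Distinct from an *undefined* (saturated) K2P distance: here there is
    no data at all to compute any distance from.
    """


class AnalysisError(TaxgapError):
    """A request that is ill-posed for the given data (e.g. NN analysis
    on a single species, SNP density on zero loci)."""


class PreconditionError(AnalysisError):
    """An operation invoked on data that has not passed a required
    upstream filter."""


# ---------------------------------------------------------------------------
# Sequence encoding shared by the simulator and the distance code
# ---------------------------------------------------------------------------

# A=0, G=1, C=2, T=3: XOR 1 maps to the transition partner (A<->G, C<->T)
# and XOR 2 / XOR 3 map to the two transversion partners.
_BASES = "AGCT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to codes; anything outside {A,C,G,T} becomes -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


# ===========================================================================
# Section 1 — synthetic data
# ===========================================================================


@dataclass(frozen=True)
class BarcodeSimConfig:
    """Settings for a star-genealogy barcode simulation.

    ``d_inter`` is the expected divergence (substitutions/site) between
    two species *ancestors*, so each ancestor sits ``d_inter / 2`` from
    the root; ``d_intra`` is the branch length from a species ancestor
    to each sampled specimen. ``kappa`` is the transition/transversion
    rate ratio of the K2P process.
    """

    n_species: int
    per_species_n: tuple[int, ...]
    seq_length: int = 658
    d_inter: float = 0.04
    d_intra: float = 0.002
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_species_n", tuple(self.per_species_n))
        if self.n_species < 1 or len(self.per_species_n) != self.n_species:
            raise InvalidParameterError(
                "per_species_n must list one count per species"
            )
        if any(n < 1 for n in self.per_species_n):
            raise InvalidParameterError("per_species_n entries must be >= 1")
        if self.seq_length < 1:
            raise InvalidParameterError("seq_length must be >= 1")
        for name, d in (("d_inter", self.d_inter), ("d_intra", self.d_intra)):
            if not (0.0 <= d < 0.75):
                raise InvalidParameterError(f"{name} must lie in [0, 0.75)")
        if not self.kappa > 0:
            raise InvalidParameterError("kappa must be > 0")


@dataclass(frozen=True)
class GenotypeSimConfig:
    """Settings for a genotype-matrix simulation with planted structure.

    ``n_planted_fixed`` tags each receive a single fully genotyped
    bi-allelic site whose alleles are disjoint between the two groups;
    the remaining tags carry 1..``sites_per_tag_max`` non-diagnostic
    sites which may be heterozygous, tri-allelic or invariant, with
    missing calls injected at ``missing_rate`` (never inside a planted
    tag, so the planted signal survives the completeness filter).
    """

    group_sizes: tuple[int, int] = (8, 5)
    n_tags: int = 66
    sites_per_tag_max: int = 4
    n_planted_fixed: int = 30
    missing_rate: float = 0.0
    het_rate: float = 0.1
    triallelic_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_sizes", tuple(self.group_sizes))
        if len(self.group_sizes) != 2 or any(n < 1 for n in self.group_sizes):
            raise InvalidParameterError("group_sizes must be two counts >= 1")
        if self.sites_per_tag_max < 1:
            raise InvalidParameterError("sites_per_tag_max must be >= 1")
        if not 0 <= self.n_planted_fixed <= self.n_tags:
            raise InvalidParameterError("n_planted_fixed must be <= n_tags")
        for name in ("missing_rate", "het_rate", "triallelic_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground-truth bookkeeping emitted next to a simulated matrix."""

    planted_fixed_sites: list[tuple[str, int]]
    planted_pis_count: int
    site_provenance: dict[tuple[str, int], str]  # planted|background|invariant
    complete_tags: list[str]  # tags with zero injected missing calls
    single_biallelic_tags: list[str]  # exactly one variable site, 2 alleles
    het_calls_per_sample: dict[str, int]
    n_variable_sites: int


def evolve_sequence(
    parent: str, d: float, kappa: float, rng: np.random.Generator
) -> str:
    """Mutate ``parent`` along a branch of length ``d`` under K2P.

    Each site evolves independently under the continuous-time K2P chain
    with transition/transversion rate ratio ``kappa``, scaled so that
    ``d`` is the expected number of substitutions per site. With
    ``a = kappa/(kappa+2)`` and ``b = 1/(kappa+2)`` the site-change
    probabilities at branch length ``d`` are::

        P(transition)        = 1/4 + 1/4 exp(-4 b d) - 1/2 exp(-2 (a+b) d)
        P(each transversion) = 1/4 - 1/4 exp(-4 b d)

    which is the exact generative counterpart of the K2P distance
    estimator: plugging these P, Q back into it returns ``d``.
    """
    if not (0.0 <= d < 0.75):
        raise InvalidParameterError("branch length d must lie in [0, 0.75)")
    if not kappa > 0:
        raise InvalidParameterError("kappa must be > 0")
    codes = _encode(parent)
    if np.any(codes < 0):
        raise InputError("parent sequence must be over {A,C,G,T}")
    b = 1.0 / (kappa + 2.0)
    a = kappa / (kappa + 2.0)
    e_ts = math.exp(-2.0 * (a + b) * d)
    e_tv = math.exp(-4.0 * b * d)
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv_each = 0.25 - 0.25 * e_tv
    p_same = 1.0 - p_ts - 2.0 * p_tv_each
    # category per site: 0 same, 1 transition, 2/3 the two transversions
    cuts = np.cumsum([p_same, p_ts, p_tv_each])
    cat = np.searchsorted(cuts, rng.random(codes.shape[0]), side="right")
    child = codes ^ cat.astype(np.int8)  # XOR trick: cat 0 is identity
    return _decode(child)


def simulate_barcode_dataset(
    config: BarcodeSimConfig,
) -> tuple["BarcodeAlignment", dict[str, str]]:
    """Simulate an aligned barcode dataset on a star genealogy.

    One random ancestral sequence (uniform base composition); each
    species ancestor evolves from it by ``d_inter / 2``; each specimen
    evolves from its species ancestor by ``d_intra``. Expected pairwise
    divergences are therefore ``2 * d_intra`` within a species and
    ``d_inter + 2 * d_intra`` between species. Deterministic given the
    seed; sites are always iterated left to right.
    """
    rng = np.random.default_rng(config.seed)
    root = _decode(rng.integers(0, 4, size=config.seq_length))
    records: list[SequenceRecord] = []
    species_map: dict[str, str] = {}
    for i, n in enumerate(config.per_species_n):
        species = f"sp{i + 1:02d}"
        ancestor = evolve_sequence(root, config.d_inter / 2.0, config.kappa, rng)
        for j in range(n):
            sample_id = f"{species}_{j + 1:03d}"
            seq = evolve_sequence(ancestor, config.d_intra, config.kappa, rng)
            records.append(SequenceRecord(sample_id, species, seq))
            species_map[sample_id] = species
    return BarcodeAlignment(records), species_map


def _nondiagnostic_site(
    tag: str,
    pos: int,
    n1: int,
    n2: int,
    rng: np.random.Generator,
    het_rate: float,
    triallelic_rate: float,
) -> "Site":
    """Build a variable site guaranteed NOT to be a fixed difference:
    the first allele is forced to appear in a called genotype of both
    groups."""
    x, y = rng.choice(4, size=2, replace=False)
    ax, ay = _BASES[x], _BASES[y]
    n = n1 + n2
    gts: list[Optional[tuple[str, str]]] = []
    for _ in range(n):
        if rng.random() < het_rate:
            gts.append(tuple(sorted((ax, ay))))
        else:
            allele = ax if rng.random() < 0.5 else ay
            gts.append((allele, allele))
    # anchor the shared allele in both groups and keep the site variable
    gts[0] = (ax, ax)
    gts[n1] = (ax, ax)
    if all(g == (ax, ax) for g in gts):
        gts[-1] = (ay, ay)
    if rng.random() < triallelic_rate:
        others = [b for b in _BASES if b not in (ax, ay)]
        az = others[int(rng.integers(len(others)))]
        # put the third allele on a non-anchor sample, het with the shared one
        k = 1 if n1 > 1 else n1 + 1 if n2 > 1 else None
        if k is not None:
            gts[k] = tuple(sorted((ax, az)))
    return Site(tag, pos, tuple(gts))


def simulate_genotype_matrix(
    config: GenotypeSimConfig,
) -> tuple["GenotypeMatrix", SimTruth]:
    """Simulate a two-group genotype matrix with planted fixed differences.

    Exactly ``n_planted_fixed`` tags carry a single bi-allelic site
    whose alleles are disjoint between the groups and genotyped in every
    sample; the other tags carry non-diagnostic sites (shared allele
    enforced) with optional heterozygous calls, tri-allelic sites,
    invariant sites and missing data. Sample ids are ``g1_*``/``g2_*``
    with group labels ``group1``/``group2``.
    """
    n1, n2 = config.group_sizes
    rng = np.random.default_rng(config.seed)
    samples = [f"g1_{i + 1:02d}" for i in range(n1)] + [
        f"g2_{i + 1:02d}" for i in range(n2)
    ]
    planted_tags = set(
        int(t)
        for t in rng.choice(config.n_tags, size=config.n_planted_fixed, replace=False)
    )
    sites: list[Site] = []
    provenance: dict[tuple[str, int], str] = {}
    planted_sites: list[tuple[str, int]] = []
    tags_with_missing: set[str] = set()
    all_tags: list[str] = []
    for t in range(config.n_tags):
        tag = f"tag{t + 1:04d}"
        all_tags.append(tag)
        if t in planted_tags:
            x, y = rng.choice(4, size=2, replace=False)
            ax, ay = _BASES[x], _BASES[y]
            gts = tuple(
                (ax, ax) if i < n1 else (ay, ay) for i in range(n1 + n2)
            )
            sites.append(Site(tag, 0, gts))
            provenance[(tag, 0)] = "planted"
            planted_sites.append((tag, 0))
            continue
        n_sites = int(rng.integers(1, config.sites_per_tag_max + 1))
        for pos in range(n_sites):
            if rng.random() < 0.2:  # invariant sites also occur on real tags
                allele = _BASES[int(rng.integers(4))]
                gts_list: list[Optional[tuple[str, str]]] = [
                    (allele, allele)
                ] * (n1 + n2)
                site = Site(tag, pos, tuple(gts_list))
                provenance[(tag, pos)] = "invariant"
            else:
                site = _nondiagnostic_site(
                    tag, pos, n1, n2, rng, config.het_rate, config.triallelic_rate
                )
                provenance[(tag, pos)] = "background"
            if config.missing_rate > 0:
                gts_list = list(site.genotypes)
                for i in range(n1 + n2):
                    if rng.random() < config.missing_rate:
                        gts_list[i] = None
                        tags_with_missing.add(tag)
                site = Site(tag, pos, tuple(gts_list))
            sites.append(site)
    gm = GenotypeMatrix(samples, sites)
    planted_pis = len(planted_sites) if (n1 >= 2 and n2 >= 2) else 0
    het_counts = {
        s: sum(
            1
            for site in sites
            if (g := site.genotypes[i]) is not None and g[0] != g[1]
        )
        for i, s in enumerate(samples)
    }
    truth = SimTruth(
        planted_fixed_sites=sorted(planted_sites),
        planted_pis_count=planted_pis,
        site_provenance=provenance,
        complete_tags=[t for t in all_tags if t not in tags_with_missing],
        single_biallelic_tags=_single_biallelic_tags(gm),
        het_calls_per_sample=het_counts,
        n_variable_sites=sum(1 for s in sites if s.is_variable),
    )
    return gm, truth


def default_group_map(config: GenotypeSimConfig) -> dict[str, str]:
    """The sample -> group labelling matching ``simulate_genotype_matrix``."""
    n1, n2 = config.group_sizes
    out = {f"g1_{i + 1:02d}": "group1" for i in range(n1)}
    out.update({f"g2_{i + 1:02d}": "group2" for i in range(n2)})
    return out


# ===========================================================================
# Section 2 — barcode distances and summaries
# ===========================================================================


@dataclass(frozen=True)
class SequenceRecord:
    sample_id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"empty sequence for {self.sample_id!r}")


@dataclass
class BarcodeAlignment:
    """Pre-aligned barcode sequences; all records the same length."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = [i for i, c in Counter(ids).items() if c > 1]
            raise InputError(f"duplicate sample ids: {dupes}")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentError(
                f"sequences are not aligned: lengths {sorted(lengths)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]


@dataclass(frozen=True)
class PairwiseSiteCounts:
    """Sufficient statistics of the K2P model for one sequence pair:
    ``n`` compared sites after pairwise deletion, ``ts`` transition and
    ``tv`` transversion differences."""

    n: int
    ts: int
    tv: int

    def __post_init__(self) -> None:
        if self.n < 0 or self.ts < 0 or self.tv < 0 or self.ts + self.tv > self.n:
            raise InvalidParameterError("need 0 <= ts + tv <= n")

    @property
    def P(self) -> float:
        if self.n == 0:
            raise NoOverlapError("no compared sites")
        return self.ts / self.n

    @property
    def Q(self) -> float:
        if self.n == 0:
            raise NoOverlapError("no compared sites")
        return self.tv / self.n


def count_site_patterns(a: str, b: str) -> PairwiseSiteCounts:
    """Tally compared/transition/transversion sites for one pair.

    Pairwise deletion: a site is compared only if both symbols are plain
    A, C, G or T — gaps, N and IUPAC ambiguity codes are treated as
    missing at that site.
    """
    if len(a) != len(b):
        raise AlignmentError(f"length mismatch: {len(a)} vs {len(b)}")
    ca, cb = _encode(a), _encode(b)
    return _count_encoded(ca, cb)


def _count_encoded(ca: np.ndarray, cb: np.ndarray) -> PairwiseSiteCounts:
    valid = (ca >= 0) & (cb >= 0)
    diff = valid & (ca != cb)
    ts = int(np.count_nonzero(diff & ((ca ^ 1) == cb)))
    return PairwiseSiteCounts(
        n=int(np.count_nonzero(valid)), ts=ts, tv=int(np.count_nonzero(diff)) - ts
    )


def k2p_distance(c: PairwiseSiteCounts) -> Optional[float]:
    """Kimura 2-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

    Returns ``None`` (a flagged *undefined*, distinct from zero) when a
    log argument is non-positive, i.e. the pair is saturated beyond the
    estimator's domain. Raises :class:`NoOverlapError` when no sites
    were compared at all.
    """
    p, q = c.P, c.Q  # raises NoOverlapError on n == 0
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def p_distance(c: PairwiseSiteCounts) -> float:
    """Uncorrected distance: differing sites / compared sites."""
    if c.n == 0:
        raise NoOverlapError("no compared sites")
    return (c.ts + c.tv) / c.n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix in proportion units.

    Undefined entries (saturated K2P, or zero-overlap pairs) are NaN in
    ``values`` and False in ``defined`` — they are flagged, never
    silently zero.
    """

    ids: list[str]
    values: np.ndarray  # square, proportions, NaN where undefined
    defined: np.ndarray  # square bool
    model: str  # "k2p" | "pdist"

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.values.shape == (n, n) and self.defined.shape == (n, n)

    def index_of(self, sample_id: str) -> int:
        return self.ids.index(sample_id)

    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.count_nonzero(~self.defined[iu]))

    def to_percent_frame(self) -> pd.DataFrame:
        """Square DataFrame in percent units (NaN where undefined)."""
        return pd.DataFrame(self.values * 100.0, index=self.ids, columns=self.ids)


def distance_matrix(aln: BarcodeAlignment, model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix under K2P or the p-distance.

    Pairs with zero overlap, or saturated under K2P, are recorded as
    undefined with a warning rather than raising.
    """
    if model not in ("k2p", "pdist"):
        raise InputError(f"unknown model {model!r}; use 'k2p' or 'pdist'")
    if len(aln) < 2:
        raise InputError("need at least 2 sequences")
    encoded = [_encode(r.sequence) for r in aln.records]
    n = len(aln)
    values = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            counts = _count_encoded(encoded[i], encoded[j])
            if counts.n == 0:
                d: Optional[float] = None
                logger.warning(
                    "no overlapping sites for pair (%s, %s); distance undefined",
                    aln.records[i].sample_id,
                    aln.records[j].sample_id,
                )
            elif model == "k2p":
                d = k2p_distance(counts)
                if d is None:
                    logger.warning(
                        "saturated pair (%s, %s): K2P undefined",
                        aln.records[i].sample_id,
                        aln.records[j].sample_id,
                    )
            else:
                d = p_distance(counts)
            if d is None:
                values[i, j] = values[j, i] = np.nan
                defined[i, j] = defined[j, i] = False
            else:
                values[i, j] = values[j, i] = d
    return DistanceMatrix(aln.sample_ids, values, defined, model)


@dataclass(frozen=True)
class SpeciesIntraSummary:
    species: str
    n: int
    mean_intra: Optional[float]  # proportion; None when n == 1
    max_intra: Optional[float]

    def __post_init__(self) -> None:
        if self.mean_intra is not None and self.max_intra is not None:
            assert self.mean_intra <= self.max_intra + 1e-12


def _species_members(
    dm: DistanceMatrix, species_map: Mapping[str, str]
) -> "OrderedDict[str, list[int]]":
    unmapped = [s for s in dm.ids if s not in species_map]
    if unmapped:
        raise InputError(f"samples missing from species map: {unmapped}")
    members: OrderedDict[str, list[int]] = OrderedDict()
    for i, s in enumerate(dm.ids):
        members.setdefault(species_map[s], []).append(i)
    return members


def intraspecific_summary(
    dm: DistanceMatrix, species_map: Mapping[str, str]
) -> list[SpeciesIntraSummary]:
    """Mean and maximum within-species distance, per species.

    Singletons report mean and max as not available (``None``).
    Undefined pairs are excluded from the mean/max with a warning.
    """
    out = []
    for species, idx in _species_members(dm, species_map).items():
        if len(idx) == 1:
            out.append(SpeciesIntraSummary(species, 1, None, None))
            continue
        vals = []
        n_undef = 0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                if dm.defined[i, j]:
                    vals.append(dm.values[i, j])
                else:
                    n_undef += 1
        if n_undef:
            logger.warning(
                "%d undefined intraspecific pair(s) excluded for %s",
                n_undef,
                species,
            )
        if vals:
            out.append(
                SpeciesIntraSummary(
                    species, len(idx), float(np.mean(vals)), float(np.max(vals))
                )
            )
        else:
            out.append(SpeciesIntraSummary(species, len(idx), None, None))
    return out


@dataclass(frozen=True)
class SpeciesNN:
    species: str
    nn_species: Optional[str]
    nn_distance: Optional[float]  # proportion


def nearest_neighbor_analysis(
    dm: DistanceMatrix, species_map: Mapping[str, str]
) -> list[SpeciesNN]:
    """Nearest-neighbour species per species.

    The NN distance of a focal species is the minimum pairwise distance
    from any of its members to any member of another species; the NN
    species is that other species. Ties are broken by lexicographic
    species name (and logged).
    """
    members = _species_members(dm, species_map)
    if len(members) < 2:
        raise AnalysisError("nearest-neighbour analysis needs >= 2 species")
    out = []
    for focal, idx in members.items():
        best: dict[str, float] = {}
        n_undef = 0
        for other, jdx in members.items():
            if other == focal:
                continue
            d_min = math.inf
            for i in idx:
                for j in jdx:
                    if dm.defined[i, j]:
                        d_min = min(d_min, dm.values[i, j])
                    else:
                        n_undef += 1
            if math.isfinite(d_min):
                best[other] = d_min
        if n_undef:
            logger.warning(
                "%d undefined interspecific pair(s) skipped for %s", n_undef, focal
            )
        if not best:
            logger.warning("no defined interspecific distance for %s", focal)
            out.append(SpeciesNN(focal, None, None))
            continue
        d_nn = min(best.values())
        ties = sorted(s for s, d in best.items() if d == d_nn)
        if len(ties) > 1:
            logger.info(
                "NN tie for %s between %s; lexicographic winner %s",
                focal,
                ties,
                ties[0],
            )
        out.append(SpeciesNN(focal, ties[0], d_nn))
    return out


@dataclass(frozen=True)
class NNSummary:
    """Min / mean / max / SE over the per-species NN distances, where
    SE = sample standard deviation / sqrt(k) over the k values."""

    min: float
    mean: float
    max: float
    se: float


def nn_overall_summary(nn_distances: Sequence[float]) -> NNSummary:
    """Summarise per-species NN distances (any consistent unit)."""
    vals = [float(v) for v in nn_distances]
    if not vals:
        raise InputError("empty list of NN distances")
    k = len(vals)
    se = float(np.std(vals, ddof=1) / math.sqrt(k)) if k > 1 else 0.0
    return NNSummary(
        min=float(np.min(vals)), mean=float(np.mean(vals)), max=float(np.max(vals)), se=se
    )


def threshold_cluster(
    dm: DistanceMatrix, threshold: float, ignore_undefined: bool = False
) -> dict[str, str]:
    """Single-linkage clusters at a distance threshold.

    Samples whose distance is strictly below ``threshold`` are linked;
    clusters are the connected components, labelled by their smallest
    member sample id. Undefined distances raise unless
    ``ignore_undefined`` (then treated as above threshold, logged).
    This is a transparent proxy for BIN-style OTU assignment.
    """
    if threshold < 0:
        raise InvalidParameterError("threshold must be >= 0")
    n = len(dm.ids)
    n_undef = dm.n_undefined_pairs()
    if n_undef and not ignore_undefined:
        raise AnalysisError(
            f"{n_undef} undefined pair distance(s); rerun with ignore_undefined "
            "to treat them as above threshold"
        )
    if n_undef:
        logger.warning(
            "%d undefined pair(s) treated as above the %.4g threshold",
            n_undef,
            threshold,
        )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dm.defined[i, j] and dm.values[i, j] < threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[str]] = {}
    for i, s in enumerate(dm.ids):
        clusters.setdefault(find(i), []).append(s)
    labels = {root: min(mems) for root, mems in clusters.items()}
    return {s: labels[find(i)] for i, s in enumerate(dm.ids)}


# ===========================================================================
# Section 3 — genotype matrices and diagnostic SNPs
# ===========================================================================

Genotype = Optional[tuple[str, str]]  # unordered allele pair, or None


@dataclass(frozen=True)
class Site:
    """One site of a genotype matrix: a tag (locus) id, a 0-based
    position within the tag, and one genotype per sample."""

    tag: str
    pos: int
    genotypes: tuple[Genotype, ...]

    def __post_init__(self) -> None:
        for g in self.genotypes:
            if g is None:
                continue
            if len(g) != 2 or any(a not in "ACGT" for a in g):
                raise InputError(f"bad genotype {g!r} at {self.tag}:{self.pos + 1}")
        if self.genotypes and any(
            g is not None and g != tuple(sorted(g)) for g in self.genotypes
        ):
            object.__setattr__(
                self,
                "genotypes",
                tuple(
                    tuple(sorted(g)) if g is not None else None
                    for g in self.genotypes
                ),
            )

    @property
    def observed_alleles(self) -> set[str]:
        return {a for g in self.genotypes if g is not None for a in g}

    @property
    def is_variable(self) -> bool:
        return len(self.observed_alleles) >= 2

    @property
    def n_missing(self) -> int:
        return sum(1 for g in self.genotypes if g is None)


@dataclass
class GenotypeMatrix:
    """Samples x sites genotype matrix, sites grouped into tags."""

    samples: list[str]
    sites: list[Site]

    def __post_init__(self) -> None:
        keys = [(s.tag, s.pos) for s in self.sites]
        if len(set(keys)) != len(keys):
            dupes = [k for k, c in Counter(keys).items() if c > 1]
            raise InputError(f"duplicate (tag, pos) sites: {dupes[:5]}")
        for s in self.sites:
            if len(s.genotypes) != len(self.samples):
                raise InputError(
                    f"site {s.tag}:{s.pos + 1} has {len(s.genotypes)} genotypes "
                    f"for {len(self.samples)} samples"
                )

    @property
    def tags(self) -> list[str]:
        seen: OrderedDict[str, None] = OrderedDict()
        for s in self.sites:
            seen.setdefault(s.tag)
        return list(seen)

    def sites_by_tag(self) -> "OrderedDict[str, list[Site]]":
        out: OrderedDict[str, list[Site]] = OrderedDict()
        for s in self.sites:
            out.setdefault(s.tag, []).append(s)
        return out

    def subset_tags(self, keep: Iterable[str]) -> "GenotypeMatrix":
        keep_set = set(keep)
        return GenotypeMatrix(
            list(self.samples), [s for s in self.sites if s.tag in keep_set]
        )

    def reorder_samples(self, order: Sequence[str]) -> "GenotypeMatrix":
        if sorted(order) != sorted(self.samples):
            raise InputError("reorder must permute the existing samples")
        idx = [self.samples.index(s) for s in order]
        return GenotypeMatrix(
            list(order),
            [
                Site(s.tag, s.pos, tuple(s.genotypes[i] for i in idx))
                for s in self.sites
            ],
        )


def filter_complete_loci(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only tags genotyped in every sample at every site (0% missing)."""
    if not gm.samples or not gm.sites:
        raise InputError("empty genotype matrix")
    complete = [
        tag
        for tag, sites in gm.sites_by_tag().items()
        if all(s.n_missing == 0 for s in sites)
    ]
    dropped = len(gm.tags) - len(complete)
    if dropped:
        logger.info("completeness filter dropped %d tag(s)", dropped)
    return gm.subset_tags(complete)


def _single_biallelic_tags(gm: GenotypeMatrix) -> list[str]:
    out = []
    for tag, sites in gm.sites_by_tag().items():
        variable = [s for s in sites if s.is_variable]
        if len(variable) == 1 and len(variable[0].observed_alleles) == 2:
            out.append(tag)
    return out


def select_single_biallelic_snp_tags(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep tags with exactly one variable site, that site bi-allelic.

    "Bi-allelic" is judged on the alleles *observed in the genotypes* of
    the analysed samples, not on declared-but-unobserved alternates.
    """
    keep = _single_biallelic_tags(gm)
    dropped = len(gm.tags) - len(keep)
    if dropped:
        logger.info("single-bi-allelic-SNP filter dropped %d tag(s)", dropped)
    return gm.subset_tags(keep)


@dataclass(frozen=True)
class SNPCounts:
    """SNP / PIS tallies over a genotype matrix.

    ``snp_density`` (SNPs per locus) is derived, never stored."""

    n_loci_retained: int
    n_snps: int
    n_pis: int

    def __post_init__(self) -> None:
        if self.n_pis > self.n_snps:
            raise InvalidParameterError("n_pis cannot exceed n_snps")

    @property
    def snp_density(self) -> float:
        if self.n_loci_retained == 0:
            raise AnalysisError("SNP density undefined for zero loci")
        return self.n_snps / self.n_loci_retained


def _is_pis(site: Site) -> bool:
    # an allele supports informativeness when carried by >= 2 samples
    # (a heterozygote carries both of its alleles)
    carriers: Counter[str] = Counter()
    for g in site.genotypes:
        if g is not None:
            for a in set(g):
                carriers[a] += 1
    return sum(1 for c in carriers.values() if c >= 2) >= 2


def count_snps_and_pis(gm: GenotypeMatrix) -> SNPCounts:
    """Count variable sites (SNPs) and parsimony-informative sites.

    A site is parsimony-informative when at least two distinct alleles
    are each carried by at least two samples. Invariant sites count in
    neither tally. Density is SNPs per tag over the tags present.
    """
    n_loci = len(gm.tags)
    if n_loci == 0:
        raise AnalysisError("SNP density undefined for zero loci")
    variable = [s for s in gm.sites if s.is_variable]
    return SNPCounts(
        n_loci_retained=n_loci,
        n_snps=len(variable),
        n_pis=sum(1 for s in variable if _is_pis(s)),
    )


@dataclass(frozen=True)
class DiagnosticSNP:
    """A fixed allelic difference: the site's allele sets in the two
    groups are disjoint and every sample is genotyped."""

    tag: str
    pos: int  # 0-based; printed 1-based
    group1_alleles: frozenset[str]
    group2_alleles: frozenset[str]

    def __post_init__(self) -> None:
        assert self.group1_alleles and self.group2_alleles
        assert not (self.group1_alleles & self.group2_alleles)


def _two_group_indices(
    samples: Sequence[str], groups: Mapping[str, str]
) -> tuple[str, list[int], str, list[int]]:
    unassigned = [s for s in samples if s not in groups]
    if unassigned:
        raise InputError(f"samples missing from group map: {unassigned}")
    labels = sorted({groups[s] for s in samples})
    if len(labels) != 2:
        raise InputError(f"need exactly two groups, got {labels}")
    g1 = [i for i, s in enumerate(samples) if groups[s] == labels[0]]
    g2 = [i for i, s in enumerate(samples) if groups[s] == labels[1]]
    return labels[0], g1, labels[1], g2


def _check_prefiltered(gm: GenotypeMatrix) -> None:
    for tag, sites in gm.sites_by_tag().items():
        if any(s.n_missing > 0 for s in sites):
            raise PreconditionError(
                f"tag {tag} has missing genotypes; apply filter_complete_loci first"
            )
        variable = [s for s in sites if s.is_variable]
        if len(variable) != 1 or len(variable[0].observed_alleles) != 2:
            raise PreconditionError(
                f"tag {tag} is not a single-bi-allelic-SNP tag; apply "
                "select_single_biallelic_snp_tags first"
            )


def find_fixed_differences(
    gm: GenotypeMatrix, groups: Mapping[str, str]
) -> list[DiagnosticSNP]:
    """Sites whose allele sets are disjoint between the two groups.

    A heterozygote carrying the other group's allele disqualifies the
    site — this is the strictest reading of "fixed". Requires a matrix
    that already passed the completeness and single-bi-allelic-SNP
    filters (raises :class:`PreconditionError` otherwise). Output is
    sorted by (tag, position).
    """
    _, g1, _, g2 = _two_group_indices(gm.samples, groups)
    _check_prefiltered(gm)
    out = []
    for site in gm.sites:
        a1 = {a for i in g1 if (g := site.genotypes[i]) is not None for a in g}
        a2 = {a for i in g2 if (g := site.genotypes[i]) is not None for a in g}
        if a1 and a2 and not (a1 & a2) and site.n_missing == 0:
            out.append(
                DiagnosticSNP(site.tag, site.pos, frozenset(a1), frozenset(a2))
            )
    return sorted(out, key=lambda d: (d.tag, d.pos))


@dataclass(frozen=True)
class SampleHetStats:
    sample_id: str
    n_called: int
    n_het: int
    heterozygosity: Optional[float]  # None when nothing was called

    def __post_init__(self) -> None:
        if self.heterozygosity is not None:
            assert 0.0 <= self.heterozygosity <= 1.0


def observed_heterozygosity(gm: GenotypeMatrix) -> list[SampleHetStats]:
    """Per-sample observed heterozygosity: het calls / called sites.

    Counted over every site of every tag present in the matrix,
    invariant sites included. A sample with zero called sites is flagged
    not-available rather than reported as zero.
    """
    out = []
    for i, sample in enumerate(gm.samples):
        called = het = 0
        for site in gm.sites:
            g = site.genotypes[i]
            if g is None:
                continue
            called += 1
            het += g[0] != g[1]
        if called == 0:
            logger.warning("sample %s has no called sites", sample)
            out.append(SampleHetStats(sample, 0, 0, None))
        else:
            out.append(SampleHetStats(sample, called, het, het / called))
    return out


# ===========================================================================
# Section 4 — file formats
# ===========================================================================


def write_fasta(aln: BarcodeAlignment, path: str | Path) -> None:
    """Write the alignment as FASTA wrapped at 80 columns."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio.SeqIO.FastaIO import FastaWriter

    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=80)
        writer.write_file(
            SeqRecord(Seq(r.sequence), id=r.sample_id, description="")
            for r in aln.records
        )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no sequences in {path}")
    return records


def write_two_column_tsv(
    mapping: Mapping[str, str], path: str | Path, header: tuple[str, str]
) -> None:
    with open(path, "w") as fh:
        fh.write(f"{header[0]}\t{header[1]}\n")
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


def read_two_column_tsv(path: str | Path) -> dict[str, str]:
    """Read ``sample_id<TAB>label`` (optional header line, '#' comments)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{ln}: expected two tab-separated columns")
            if ln == 1 and parts[0] in ("sample_id", "sample"):
                continue
            out[parts[0]] = parts[1]
    if not out:
        raise InputError(f"no entries in {path}")
    return out


def build_alignment(
    fasta_records: Sequence[tuple[str, str]], species_map: Mapping[str, str]
) -> BarcodeAlignment:
    missing = [sid for sid, _ in fasta_records if sid not in species_map]
    if missing:
        raise InputError(f"samples missing from species map: {missing}")
    return BarcodeAlignment(
        [SequenceRecord(sid, species_map[sid], seq) for sid, seq in fasta_records]
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as minimal VCF 4.2: CHROM = tag id, POS = 1-based
    site within tag, unphased GT, ``./.`` for missing. REF is the
    alphabetically first observed allele (the simulator carries no
    reference genome)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for tag in gm.tags:
            fh.write(f"##contig=<ID={tag}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for site in gm.sites:
            alleles = sorted(site.observed_alleles) or ["A"]
            ref, alts = alleles[0], alleles[1:]
            index = {a: k for k, a in enumerate(alleles)}
            cells = []
            for g in site.genotypes:
                if g is None:
                    cells.append("./.")
                else:
                    i, j = sorted(index[a] for a in g)
                    cells.append(f"{i}/{j}")
            fh.write(
                f"{site.tag}\t{site.pos + 1}\t.\t{ref}\t"
                f"{','.join(alts) if alts else '.'}\t.\tPASS\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF 4.2 genotype matrix (GT field required; CHROM = tag).

    Alleles declared in ALT but observed in no genotype are ignored (and
    logged): the bi-allelic filter judges observed genotypes only.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise InputError(f"no samples in {path}")
    sites = []
    for v in vcf:
        gts: list[Genotype] = []
        observed: set[str] = set()
        for cell in v.gt_bases:
            alleles = cell.replace("|", "/").split("/")
            if alleles[0] in (".", ""):
                gts.append(None)
                continue
            if len(alleles) != 2:
                raise InputError(
                    f"{path}: non-diploid genotype {cell!r} at {v.CHROM}:{v.POS}"
                )
            if any(a not in "ACGT" for a in alleles):
                raise InputError(
                    f"{path}: unsupported allele in {cell!r} at {v.CHROM}:{v.POS}"
                )
            pair = tuple(sorted(alleles))
            observed.update(pair)
            gts.append(pair)
        declared = {v.REF, *[a for a in v.ALT if a != "."]}
        unused = declared - observed - {"."}
        if unused:
            logger.info(
                "%s:%d declares unobserved allele(s) %s; ignored",
                v.CHROM,
                v.POS,
                sorted(unused),
            )
        sites.append(Site(v.CHROM, v.POS - 1, tuple(gts)))
    if not sites:
        raise InputError(f"no variant records in {path}")
    return GenotypeMatrix(samples, sites)


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Rows = sites: ``tag_id  pos  <one A/T-style column per sample>``
    with ``NN`` for missing; pos is 1-based."""
    with open(path, "w") as fh:
        fh.write("tag_id\tpos\t" + "\t".join(gm.samples) + "\n")
        for site in gm.sites:
            cells = [
                "NN" if g is None else f"{g[0]}/{g[1]}" for g in site.genotypes
            ]
            fh.write(f"{site.tag}\t{site.pos + 1}\t" + "\t".join(cells) + "\n")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[:2] != ["tag_id", "pos"]:
            raise InputError(f"{path}: expected header 'tag_id\\tpos\\t<samples>'")
        samples = header[2:]
        sites = []
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise InputError(f"{path}:{ln}: wrong column count")
            tag, pos = parts[0], int(parts[1]) - 1
            gts: list[Genotype] = []
            for cell in parts[2:]:
                if cell == "NN":
                    gts.append(None)
                elif (
                    len(cell) == 3
                    and cell[1] == "/"
                    and cell[0] in "ACGT"
                    and cell[2] in "ACGT"
                ):
                    gts.append(tuple(sorted((cell[0], cell[2]))))
                else:
                    raise InputError(f"{path}:{ln}: bad genotype {cell!r}")
            sites.append(Site(tag, pos, tuple(gts)))
    if not sites:
        raise InputError(f"no sites in {path}")
    return GenotypeMatrix(samples, sites)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Dispatch on extension: ``.vcf`` or the TSV dialect."""
    if str(path).endswith(".vcf"):
        return read_vcf(path)
    return read_genotype_tsv(path)


def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "planted_fixed_sites": [
            {"tag": t, "pos": p + 1} for t, p in truth.planted_fixed_sites
        ],
        "planted_pis_count": truth.planted_pis_count,
        "site_provenance": [
            {"tag": t, "pos": p + 1, "kind": kind}
            for (t, p), kind in truth.site_provenance.items()
        ],
        "complete_tags": truth.complete_tags,
        "single_biallelic_tags": truth.single_biallelic_tags,
        "het_calls_per_sample": truth.het_calls_per_sample,
        "n_variable_sites": truth.n_variable_sites,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ===========================================================================
# Section 5 — pipelines and reports
# ===========================================================================


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    tool_version: str
    config: dict
    stage_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2) + "\n"


def _fmt_pct(value: Optional[float]) -> str:
    """Proportions to Table-style percent with 2 decimals; N/A when absent."""
    return "N/A" if value is None else f"{value * 100.0:.2f}"


def run_barcode_pipeline(
    fasta: str | Path,
    species_tsv: str | Path,
    model: str = "k2p",
    threshold: float = 0.02,
    out_prefix: Optional[str] = None,
    ignore_undefined: bool = False,
) -> tuple[pd.DataFrame, NNSummary, dict[str, str], RunReport]:
    """Barcode-gap pipeline: distances -> intraspecific and NN summaries
    -> overall NN summary -> threshold clusters.

    Returns the Table-style per-species report (percent units), the NN
    summary (percent), the cluster assignment and a RunReport. With
    ``out_prefix`` set, also writes ``<prefix>.distmatrix.tsv``,
    ``<prefix>.species_summary.tsv``, ``<prefix>.nn_summary.json``,
    ``<prefix>.clusters.tsv`` and ``<prefix>.report.json``.
    """
    report = RunReport(
        __version__,
        {
            "fasta": str(fasta),
            "species": str(species_tsv),
            "model": model,
            "threshold": threshold,
            "ignore_undefined": ignore_undefined,
        },
    )
    aln = build_alignment(read_fasta(fasta), read_two_column_tsv(species_tsv))
    species_map = {r.sample_id: r.species for r in aln.records}
    report.stage_counts["sequences"] = len(aln)
    dm = distance_matrix(aln, model=model)
    n_undef = dm.n_undefined_pairs()
    report.stage_counts["undefined_pairs"] = n_undef
    if n_undef:
        report.warnings.append(f"{n_undef} undefined pairwise distance(s)")
    intra = intraspecific_summary(dm, species_map)
    nn = nearest_neighbor_analysis(dm, species_map)
    nn_by_species = {r.species: r for r in nn}
    rows = []
    for s in intra:
        r = nn_by_species[s.species]
        rows.append(
            {
                "species": s.species,
                "n": s.n,
                "mean_intra": _fmt_pct(s.mean_intra),
                "max_intra": _fmt_pct(s.max_intra),
                "nn_species": r.nn_species if r.nn_species is not None else "N/A",
                "nn_distance": _fmt_pct(r.nn_distance),
            }
        )
    table = pd.DataFrame(rows)
    nn_vals = [r.nn_distance * 100.0 for r in nn if r.nn_distance is not None]
    summary = nn_overall_summary(nn_vals)
    clusters = threshold_cluster(dm, threshold, ignore_undefined=ignore_undefined)
    report.stage_counts["species"] = len(intra)
    report.stage_counts["clusters"] = len(set(clusters.values()))
    if out_prefix is not None:
        dm.to_percent_frame().to_csv(
            f"{out_prefix}.distmatrix.tsv", sep="\t", na_rep="NA", float_format="%.6f"
        )
        table.to_csv(f"{out_prefix}.species_summary.tsv", sep="\t", index=False)
        Path(f"{out_prefix}.nn_summary.json").write_text(
            json.dumps(
                {k: round(v, 2) for k, v in asdict(summary).items()}, indent=2
            )
            + "\n"
        )
        write_two_column_tsv(
            clusters, f"{out_prefix}.clusters.tsv", ("sample_id", "cluster")
        )
        Path(f"{out_prefix}.report.json").write_text(report.to_json())
    return table, summary, clusters, report


def run_snp_pipeline(
    genotypes: str | Path | GenotypeMatrix,
    groups: str | Path | Mapping[str, str],
    out_prefix: Optional[str] = None,
    prefilter: bool = True,
) -> tuple[SNPCounts, list[DiagnosticSNP], list[SampleHetStats], RunReport]:
    """Diagnostic-SNP pipeline: completeness filter -> single-bi-allelic
    -SNP filter -> SNP/PIS counts + fixed differences + per-sample
    observed heterozygosity.

    ``prefilter=False`` skips the two filters, in which case
    :func:`find_fixed_differences` enforces its precondition and raises
    on unfiltered input. With ``out_prefix`` set, writes
    ``<prefix>.diagnostics.tsv``, ``<prefix>.counts.json``,
    ``<prefix>.heterozygosity.tsv`` and ``<prefix>.report.json``.
    """
    gm = genotypes if isinstance(genotypes, GenotypeMatrix) else read_genotypes(genotypes)
    group_map = groups if isinstance(groups, Mapping) else read_two_column_tsv(groups)
    report = RunReport(
        __version__,
        {
            "genotypes": str(genotypes) if not isinstance(genotypes, GenotypeMatrix) else "<in-memory>",
            "groups": "<in-memory>" if isinstance(groups, Mapping) else str(groups),
            "prefilter": prefilter,
        },
    )
    report.stage_counts["tags_in"] = len(gm.tags)
    report.stage_counts["sites_in"] = len(gm.sites)
    if prefilter:
        complete = filter_complete_loci(gm)
        report.stage_counts["tags_complete"] = len(complete.tags)
        report.stage_counts["tags_dropped_missing"] = len(gm.tags) - len(
            complete.tags
        )
        filtered = select_single_biallelic_snp_tags(complete)
        report.stage_counts["tags_retained"] = len(filtered.tags)
        report.stage_counts["tags_dropped_multi_or_nonbiallelic"] = len(
            complete.tags
        ) - len(filtered.tags)
    else:
        filtered = gm
        report.warnings.append("prefilter skipped by request")
    if not filtered.sites:
        report.warnings.append("no loci retained after filtering")
        counts = SNPCounts(0, 0, 0)
        diagnostics: list[DiagnosticSNP] = []
        het = observed_heterozygosity(gm)
    else:
        counts = count_snps_and_pis(filtered)
        diagnostics = find_fixed_differences(filtered, group_map)
        het = observed_heterozygosity(filtered)
    report.stage_counts["n_snps"] = counts.n_snps
    report.stage_counts["n_pis"] = counts.n_pis
    report.stage_counts["n_fixed_differences"] = len(diagnostics)
    if out_prefix is not None:
        with open(f"{out_prefix}.diagnostics.tsv", "w") as fh:
            fh.write("tag\tpos\tgroup1_alleles\tgroup2_alleles\n")
            for d in diagnostics:
                fh.write(
                    f"{d.tag}\t{d.pos + 1}\t"
                    f"{','.join(sorted(d.group1_alleles))}\t"
                    f"{','.join(sorted(d.group2_alleles))}\n"
                )
        counts_payload = {
            "n_loci_retained": counts.n_loci_retained,
            "n_snps": counts.n_snps,
            "n_pis": counts.n_pis,
            "snp_density": round(counts.snp_density, 2)
            if counts.n_loci_retained
            else None,
        }
        Path(f"{out_prefix}.counts.json").write_text(
            json.dumps(counts_payload, indent=2) + "\n"
        )
        with open(f"{out_prefix}.heterozygosity.tsv", "w") as fh:
            fh.write("sample_id\tn_called\tn_het\theterozygosity\n")
            for h in het:
                hz = "N/A" if h.heterozygosity is None else f"{h.heterozygosity:.6f}"
                fh.write(f"{h.sample_id}\t{h.n_called}\t{h.n_het}\t{hz}\n")
        Path(f"{out_prefix}.report.json").write_text(report.to_json())
    return counts, diagnostics, het, report


def summarize_numeric_column(
    values: Sequence[float],
) -> tuple[float, float, float, int]:
    """Arithmetic mean, min, max and count of a numeric report column."""
    vals = [float(v) for v in values]
    if not vals:
        raise InputError("empty list of values")
    return (
        float(np.mean(vals)),
        float(np.min(vals)),
        float(np.max(vals)),
        len(vals),
    )
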