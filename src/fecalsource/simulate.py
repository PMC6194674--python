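"""Synthetic fecal communities and in-silico artificial assemblages.

The generator emulates the structure the source-tracking method relies
on: each fecal source carries signature ASVs that are either exclusive
(found only in that source) or host-preferred (shared across sources
but several-fold more abundant in the home source), embedded in a large
shared pool; a freshwater background uses a disjoint ASV pool.
Intra-source sample-to-sample variability is a Dirichlet resampling of
the source profile, with the concentration calibrated so that median
pairwise Bray-Curtis dissimilarity matches a target (animal sources are
far more variable than sewage). Artificial assemblages are built the
way the sensitivity benchmark builds them: each component is
rarefied (sampled without replacement) to its share of the total depth
and the shares are concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from .seq_prep import ASVTable

__all__ = [
    "SourceProfileSpec",
    "SourcePanel",
    "MixSpec",
    "generate_source_profiles",
    "sample_community",
    "rarefy",
    "mix_assemblage",
    "largest_remainder_shares",
    "make_study_panel",
]

DEFAULT_SOURCES = ["Cat", "Cow", "Deer", "Dog", "Pig", "Sewage"]


@dataclass(frozen=True)
class SourceProfileSpec:
    """Generative parameters for a panel of synthetic source communities.

    ``exclusive_fraction`` of each source's signature ASVs occur in that
    source only; the rest are host-preferred: ``effect_size``-fold
    enriched at home and carried, at base abundance, by each other
    source with probability ``preferred_share_prob`` (at least one
    other source always carries it). ``bc_targets`` maps a source
    to the median pairwise Bray-Curtis dissimilarity its samples should
    show (defaults: 0.7 for animals, 0.3 for sewage, matching the
    intra-source consistency contrast between animal feces and sewage).
    """

    sources: tuple[str, ...] = tuple(DEFAULT_SOURCES)
    n_asvs_total: int = 500
    n_signature_per_source: int = 40
    exclusive_fraction: float = 0.30
    n_samples: int = 10
    effect_size: float = 10.0
    preferred_share_prob: float = 0.4
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    bc_targets: dict = field(default_factory=dict)
    depth: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.exclusive_fraction <= 1:
            raise ValueError("exclusive_fraction must be in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.n_signature_per_source * len(self.sources) > self.n_asvs_total:
            raise ValueError("signature ASVs exceed the total pool")

    def bc_target(self, source: str) -> float:
        if source in self.bc_targets:
            return self.bc_targets[source]
        return 0.3 if source.lower() == "sewage" else 0.7


def _random_sequences(rng: np.random.Generator, n: int, length: int = 60) -> list[str]:
    bases = np.array(list("ACGT"))
    seqs: set[str] = set()
    while len(seqs) < n:
        seqs.add("".join(rng.choice(bases, size=length)))
    return sorted(seqs)


@dataclass
class SourcePanel:
    """Generated source profiles with ground-truth ASV annotations."""

    spec: SourceProfileSpec
    profiles: pd.DataFrame  # sources x ASVs, rows sum to 1
    concentrations: dict[str, float]
    annotations: pd.DataFrame  # per ASV: role, home_source
    asv_sequences: dict[str, str]

    @property
    def asv_ids(self) -> list[str]:
        return list(self.profiles.columns)

    def planted_signatures(self, source: str) -> set[str]:
        """ASV ids planted as exclusive or preferred for ``source``
        (composite sources take the union of their members)."""
        ann = self.annotations
        members = {source}
        if source == "Pet":
            members = {"Cat", "Dog"}
        elif source == "Ruminant":
            members = {"Cow", "Deer"}
        return set(ann.index[ann.home_source.isin(members)])

    def draw_sample(self, source: str, depth: int, rng: np.random.Generator) -> np.ndarray:
        """One community: Dirichlet-resampled profile, multinomial reads."""
        p = self.profiles.loc[source].to_numpy()
        c = self.concentrations[source]
        alpha = np.where(p > 0, c * p, 0.0)
        theta = np.zeros_like(p)
        nz = alpha > 0
        theta[nz] = rng.dirichlet(alpha[nz])
        return rng.multinomial(depth, theta)

    def sample_table(
        self, seed: int, n_samples: int | None = None, depth: int | None = None,
        prefix: str = ""
    ) -> tuple[ASVTable, dict[str, str]]:
        """Draw a full training table: n_samples per source at depth."""
        rng = np.random.default_rng(seed)
        n = n_samples if n_samples is not None else self.spec.n_samples
        depth = depth if depth is not None else self.spec.depth
        rows, labels = {}, {}
        for source in self.spec.sources:
            for k in range(n):
                sid = f"{prefix}{source}_{k + 1:02d}"
                rows[sid] = self.draw_sample(source, depth, rng)
                labels[sid] = source
        counts = pd.DataFrame.from_dict(rows, orient="index", columns=self.asv_ids).astype(int)
        return ASVTable(counts, dict(self.asv_sequences)), labels


def _median_pairwise_bc(samples: np.ndarray) -> float:
    n = len(samples)
    vals = [
        braycurtis(samples[i] / samples[i].sum(), samples[j] / samples[j].sum())
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.median(vals))


def calibrate_concentration(
    profile: np.ndarray,
    target_bc: float,
    rng: np.random.Generator,
    n_draws: int = 10,
    grid: np.ndarray | None = None,
) -> float:
    """Pick the Dirichlet concentration whose draws land nearest the
    target median pairwise Bray-Curtis dissimilarity."""
    if grid is None:
        grid = np.logspace(-1, 4, 16)
    nz = profile > 0
    best_c, best_err = grid[0], np.inf
    for c in grid:
        draws = np.zeros((n_draws, len(profile)))
        for k in range(n_draws):
            draws[k, nz] = rng.dirichlet(c * profile[nz])
        err = abs(_median_pairwise_bc(draws) - target_bc)
        if err < best_err:
            best_c, best_err = c, err
    return float(best_c)


def generate_source_profiles(spec: SourceProfileSpec) -> SourcePanel:
    """Build per-source ASV probability vectors with planted signatures.

    Every ASV gets a lognormal base abundance. A source's exclusive
    signature ASVs appear (boosted ``effect_size``-fold) only in that
    source; its host-preferred signatures are boosted only at home and
    carried unboosted by a random subset of the other sources; the
    remaining shared pool is common to all.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_asvs_total
    n_sources = len(spec.sources)
    asv_ids = [f"SYN_{k + 1:04d}" for k in range(n)]
    base = rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, size=n)

    roles = pd.DataFrame({"role": "shared", "home_source": ""}, index=asv_ids)
    n_excl = int(round(spec.exclusive_fraction * spec.n_signature_per_source))
    blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    # carrier[i, j]: source j carries ASV i at base abundance
    carrier = np.ones((n, n_sources), dtype=bool)
    cursor = 0
    for si, source in enumerate(spec.sources):
        block = np.arange(cursor, cursor + spec.n_signature_per_source)
        cursor += spec.n_signature_per_source
        excl, pref = block[:n_excl], block[n_excl:]
        blocks[source] = (excl, pref)
        roles.iloc[excl, 0] = "exclusive"
        roles.iloc[pref, 0] = "preferred"
        roles.iloc[block, 1] = source
        carrier[excl, :] = False
        carrier[excl, si] = True
        if n_sources > 1:
            for i in pref:
                others = rng.random(n_sources) < spec.preferred_share_prob
                others[si] = True
                if others.sum() < 2:  # "shared" means at least one other host
                    extra = rng.choice([j for j in range(n_sources) if j != si])
                    others[extra] = True
                carrier[i] = others

    profiles = pd.DataFrame(0.0, index=list(spec.sources), columns=asv_ids)
    for si, source in enumerate(spec.sources):
        w = np.where(carrier[:, si], base, 0.0)
        excl, pref = blocks[source]
        w[excl] *= spec.effect_size
        w[pref] *= spec.effect_size
        profiles.loc[source] = w / w.sum()

    concentrations = {
        s: calibrate_concentration(profiles.loc[s].to_numpy(), spec.bc_target(s), rng)
        for s in spec.sources
    }
    sequences = dict(zip(asv_ids, _random_sequences(rng, n)))
    return SourcePanel(spec, profiles, concentrations, roles, sequences)


def make_study_panel(
    seed: int = 0,
    spec: SourceProfileSpec | None = None,
    n_background_asvs: int = 200,
    background_bc: float = 0.4,
) -> SourcePanel:
    """Fecal panel plus a freshwater background on a disjoint ASV pool.

    The combined panel shares one global ASV index so that count
    vectors from any component align; freshwater ASVs are annotated
    with role "background" and never overlap the fecal pools.
    """
    spec = spec if spec is not None else SourceProfileSpec(seed=seed)
    fecal = generate_source_profiles(spec)
    rng = np.random.default_rng(seed + 7_654_321)

    bg_ids = [f"FWB_{k + 1:04d}" for k in range(n_background_asvs)]
    bg_base = rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, size=n_background_asvs)
    bg_profile = bg_base / bg_base.sum()

    all_ids = fecal.asv_ids + bg_ids
    profiles = pd.DataFrame(0.0, index=[*spec.sources, "Freshwater"], columns=all_ids)
    profiles.loc[list(spec.sources), fecal.asv_ids] = fecal.profiles.to_numpy()
    profiles.loc["Freshwater", bg_ids] = bg_profile

    ann = pd.concat(
        [
            fecal.annotations,
            pd.DataFrame({"role": "background", "home_source": "Freshwater"}, index=bg_ids),
        ]
    )
    concentrations = dict(fecal.concentrations)
    concentrations["Freshwater"] = calibrate_concentration(
        profiles.loc["Freshwater"].to_numpy(), background_bc, rng
    )
    sequences = dict(fecal.asv_sequences)
    sequences.update(zip(bg_ids, _random_sequences(rng, n_background_asvs)))

    combined_spec = SourceProfileSpec(
        sources=(*spec.sources, "Freshwater"),
        n_asvs_total=spec.n_asvs_total + n_background_asvs,
        n_signature_per_source=spec.n_signature_per_source,
        exclusive_fraction=spec.exclusive_fraction,
        n_samples=spec.n_samples,
        effect_size=spec.effect_size,
        lognormal_mu=spec.lognormal_mu,
        lognormal_sigma=spec.lognormal_sigma,
        bc_targets={**spec.bc_targets, "Freshwater": background_bc},
        depth=spec.depth,
        seed=spec.seed,
    )
    return SourcePanel(combined_spec, profiles, concentrations, ann, sequences)


def sample_community(profile: np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Multinomial community draw of ``depth`` reads from a profile."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    profile = np.asarray(profile, dtype=float)
    if not np.isclose(profile.sum(), 1.0):
        raise ValueError("profile must sum to 1")
    return np.random.default_rng(seed).multinomial(depth, profile)


def rarefy(counts: np.ndarray, target_depth: int, seed: int | np.random.Generator) -> np.ndarray:
    """Subsample a count vector to ``target_depth`` reads without
    replacement (multivariate hypergeometric draw)."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if target_depth > total:
        raise ValueError(f"target depth {target_depth} exceeds available reads {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), target_depth)


def largest_remainder_shares(proportions: np.ndarray, depth: int) -> np.ndarray:
    """Integer shares of ``depth`` by the largest-remainder rule; sums
    exactly to depth so a 0.5% share of 100,000 reads is exact."""
    proportions = np.asarray(proportions, dtype=float)
    raw = proportions * depth
    shares = np.floor(raw).astype(int)
    short = depth - shares.sum()
    order = np.argsort(-(raw - shares), kind="stable")
    shares[order[:short]] += 1
    return shares


@dataclass(frozen=True)
class MixSpec:
    """Recipe for one artificial assemblage: component proportions
    (sources plus background) summing to 1, total depth, and the number
    of rarefying repeats (default 99)."""

    proportions: dict
    depth: int
    n_repeats: int = 99
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class MixResult:
    """Mixed assemblages (one count vector per repeat) with the
    ground-truth expected proportions that produced them."""

    counts: np.ndarray  # repeats x ASVs
    expected: dict
    shares: dict


def mix_assemblage(mix: MixSpec, components: dict[str, np.ndarray]) -> MixResult:
    """Combine rarefied component communities at defined proportions.

    Each component's count vector is rarefied to its largest-remainder
    share of the total depth, independently per repeat, and the shares
    are summed into one assemblage per repeat.
    """
    missing = set(mix.proportions) - set(components)
    if missing:
        raise ValueError(f"missing components: {sorted(missing)}")
    names = list(mix.proportions)
    shares = largest_remainder_shares(
        np.array([mix.proportions[c] for c in names]), mix.depth
    )
    for name, share in zip(names, shares):
        if share > components[name].sum():
            raise ValueError(
                f"component {name!r} has {int(components[name].sum())} reads, needs {share}"
            )
    rng = np.random.default_rng(mix.seed)
    n_asvs = len(next(iter(components.values())))
    out = np.zeros((mix.n_repeats, n_asvs), dtype=int)
    for r in range(mix.n_repeats):
        for name, share in zip(names, shares):
            if share > 0:
                out[r] += rarefy(components[name], int(share), rng)
    return MixResult(out, dict(mix.proportions), dict(zip(names, shares.tolist())))
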