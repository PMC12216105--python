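"""Coalescent simulation of per-locus phased haplotype data.

Each locus is simulated independently with msprime (ancestry with uniform
recombination, then infinite-sites-style biallelic mutations with known
ancestral state) under a :class:`~demoml.demography.DemographyEvents`
history.  The result is held as a plain 0/1 haplotype matrix with variant
positions, the in-memory currency of the summary-statistics engine.
"""

from __future__ import annotations

from dataclasses import dataclass
import msprime
import numpy as np
import tskit

from .demography import (
    DemographyEvents,
    IMParams,
    PriorSpec,
    SampleDesign,
    SCParams,
    default_priors,
    sample_parameters,
    to_demography_events,
    to_msprime_demography,
)

__all__ = [
    "LocusData",
    "ReferenceTable",
    "simulate_locus",
    "simulate_dataset",
    "build_reference_table",
    "fixture_config",
    "locus_seed",
    "locus_to_vcf",
]


@dataclass
class LocusData:
    """Phased haplotypes for one locus.

    ``haplotypes`` is a (n_haplotypes, n_sites) 0/1 matrix (0 = ancestral,
    1 = derived); rows are grouped by population per ``pop_labels``;
    ``positions`` are strictly increasing coordinates in [0, locus_length)
    (0-based, half-open convention).
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    pop_labels: np.ndarray
    locus_length: float

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        self.pop_labels = np.asarray(self.pop_labels, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must equal number of sites")
        if self.haplotypes.shape[0] != self.pop_labels.shape[0]:
            raise ValueError("pop_labels length must equal number of haplotypes")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def validate(self) -> None:
        """Check the structural invariants (entries, segregation, ordering)."""
        h = self.haplotypes
        if h.size and not np.isin(h, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if self.n_sites:
            counts = h.sum(axis=0)
            if (counts == 0).any() or (counts == self.n_hap).any():
                raise ValueError("every site must segregate in the pooled sample")
            if not (np.diff(self.positions) > 0).all():
                raise ValueError("positions must be strictly increasing")
            if (self.positions < 0).any() or (self.positions >= self.locus_length).any():
                raise ValueError("positions must lie in [0, locus_length)")
        if not (np.diff(self.pop_labels) >= 0).all():
            raise ValueError("haplotype rows must be grouped by population")

    def pop_matrix(self, pop: int) -> np.ndarray:
        return self.haplotypes[self.pop_labels == pop]


def locus_seed(master_seed: int, sim_index: int, locus_index: int) -> int:
    """Deterministic per-locus seed derived from (master seed, sim, locus)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(sim_index, locus_index))
    # msprime requires a seed in [1, 2^32)
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**32 - 1) + 1


def _tree_sequence_to_locus(ts: tskit.TreeSequence, design: SampleDesign) -> LocusData:
    n_per_pop = design.n_hap_per_pop
    pop_labels = np.repeat([0, 1], n_per_pop)
    if ts.num_sites == 0:
        return LocusData(
            haplotypes=np.zeros((2 * n_per_pop, 0), dtype=np.int8),
            positions=np.zeros(0),
            pop_labels=pop_labels,
            locus_length=design.locus_length,
        )
    geno = ts.genotype_matrix()  # (sites, samples)
    positions = ts.tables.sites.position
    # drop sites that collapsed to non-biallelic or non-segregating states
    biallelic = geno.max(axis=1) == 1
    counts = geno.sum(axis=1)
    keep = biallelic & (counts > 0) & (counts < geno.shape[1])
    geno = geno[keep]
    positions = positions[keep]
    return LocusData(
        haplotypes=np.ascontiguousarray(geno.T, dtype=np.int8),
        positions=positions,
        pop_labels=pop_labels,
        locus_length=design.locus_length,
    )


def simulate_locus(events: DemographyEvents, design: SampleDesign, seed: int) -> LocusData:
    """Simulate one locus under ``events``; deterministic given ``seed``."""
    try:
        demography = to_msprime_demography(events)
        ts = msprime.sim_ancestry(
            samples={"pop1": design.n_diploid_per_pop, "pop2": design.n_diploid_per_pop},
            demography=demography,
            sequence_length=design.locus_length,
            recombination_rate=design.recombination_rate,
            random_seed=seed,
        )
        if design.mutation_rate > 0:
            ts = msprime.sim_mutations(
                ts,
                rate=design.mutation_rate,
                random_seed=seed,
                model=msprime.BinaryMutationModel(),
                discrete_genome=False,
            )
    except Exception as exc:  # pragma: no cover - backend failure path
        raise RuntimeError(f"coalescent backend failed for events={events}") from exc
    return _tree_sequence_to_locus(ts, design)


def simulate_dataset(
    params: IMParams | SCParams,
    design: SampleDesign,
    seed: int,
    sim_index: int = 0,
) -> list[LocusData]:
    """Simulate ``design.n_loci`` independent loci for one parameter draw."""
    if design.n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    events = to_demography_events(params)
    loci = []
    for k in range(design.n_loci):
        try:
            loci.append(simulate_locus(events, design, locus_seed(seed, sim_index, k)))
        except RuntimeError as exc:
            raise RuntimeError(f"simulation failed for draw {params.as_dict()}") from exc
    return loci


@dataclass
class ReferenceTable:
    """Simulated (parameter draw, feature vector) pairs with a data split.

    ``params`` is (n_sims, n_params) in ``param_names`` order; ``features``
    is (n_sims, n_features) aligned to ``feature_names``; ``split`` assigns
    each row to 'train', 'validation' or 'test' in sampling order.
    """

    param_names: list[str]
    params: np.ndarray
    feature_names: list[str]
    features: np.ndarray
    split: np.ndarray
    seed: int | None = None
    n_rejected_draws: int = 0

    def __post_init__(self) -> None:
        if not (self.params.shape[0] == self.features.shape[0] == self.split.shape[0]):
            raise ValueError("row counts disagree")

    def rows(self, which: str) -> np.ndarray:
        return np.flatnonzero(self.split == which)

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.rows(which)
        return self.features[idx], self.params[idx]


def build_reference_table(
    model: str,
    priors: dict[str, PriorSpec],
    design: SampleDesign,
    n_sims: int,
    split_sizes: tuple[int, int, int],
    seed: int,
    stat_config=None,
    n_jobs: int = 1,
    checkpoint_path=None,
    checkpoint_every: int = 200,
    progress: bool = False,
) -> ReferenceTable:
    """Sample parameters, simulate every dataset and compute its features.

    Rows are assigned to train/validation/test in sampling order with the
    given split sizes.  With ``checkpoint_path`` set, completed feature rows
    are flushed to a ``.npz`` file every ``checkpoint_every`` simulations and
    reloaded on a rerun with the same configuration and seed.
    """
    from . import sumstats  # deferred: sumstats imports nothing from here

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if sum(split_sizes) != n_sims:
        raise ValueError(f"split sizes {split_sizes} must sum to n_sims={n_sims}")

    cfg = stat_config or sumstats.StatConfig()
    schema = sumstats.build_schema(design, cfg)
    draws, n_rejected = sample_parameters(priors, n_sims, seed)
    param_names = list(draws[0].as_dict())
    params = np.array([[d.as_dict()[k] for k in param_names] for d in draws])

    features = np.full((n_sims, len(schema)), np.nan)
    done = np.zeros(n_sims, dtype=bool)
    if checkpoint_path is not None:
        import os

        if os.path.exists(checkpoint_path):
            ck = np.load(checkpoint_path, allow_pickle=False)
            if int(ck["seed"]) == seed and ck["features"].shape == features.shape:
                features = ck["features"]
                done = ck["done"]

    def one(i: int) -> np.ndarray:
        loci = simulate_dataset(draws[i], design, seed, sim_index=i)
        return sumstats.simulation_features(loci, design, cfg, schema).values

    todo = np.flatnonzero(~done)
    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(int(i)) for i in todo)
        for i, vec in zip(todo, results):
            features[i] = vec
            done[i] = True
    else:
        iterator = todo
        if progress:
            from tqdm import tqdm  # pragma: no cover - cosmetic

            iterator = tqdm(todo, desc="simulating")
        for j, i in enumerate(iterator):
            features[int(i)] = one(int(i))
            done[int(i)] = True
            if checkpoint_path is not None and (j + 1) % checkpoint_every == 0:
                np.savez(checkpoint_path, features=features, done=done, seed=seed)
    if checkpoint_path is not None:
        np.savez(checkpoint_path, features=features, done=done, seed=seed)

    n_train, n_val, n_test = split_sizes
    split = np.array(
        ["train"] * n_train + ["validation"] * n_val + ["test"] * n_test, dtype=object
    )
    return ReferenceTable(
        param_names=param_names,
        params=params,
        feature_names=list(schema.names),
        features=features,
        split=split,
        seed=seed,
        n_rejected_draws=n_rejected,
    )


def fixture_config(model: str = "IM"):
    """A deterministic miniature configuration for tests.

    Two 100 kb loci, 4 diploids per population, priors narrowed so that
    simulation of one dataset takes well under a second.
    """
    design = SampleDesign(
        n_diploid_per_pop=4,
        n_loci=2,
        locus_length=100_000,
        recombination_rate=1.0e-8,
        mutation_rate=1.25e-8,
    )
    priors = default_priors(model)
    narrowed = {}
    for name, spec in priors.items():
        if name.startswith("n_"):
            narrowed[name] = PriorSpec(name, 500, 5000)
        else:
            narrowed[name] = spec
    return model, narrowed, design


def read_locus_vcf(path, design: SampleDesign) -> LocusData:
    """Read one locus back from a phased VCF written by :func:`locus_to_vcf`.

    Haplotype rows are the two phased alleles of each sample in file order;
    the first ``n_diploid_per_pop`` samples are population 1.  VCF positions
    are 1-based and converted back to the 0-based internal convention.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    n_dip = len(vcf.samples)
    rows = []
    positions = []
    for var in vcf:
        gt = np.array([g[:2] for g in var.genotypes], dtype=np.int8).reshape(-1)
        rows.append(gt)
        positions.append(var.POS - 1)
    vcf.close()
    hap = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((2 * n_dip, 0), dtype=np.int8)
    )
    half = n_dip // 2
    pop_labels = np.repeat([0, 1], [2 * half, 2 * (n_dip - half)])
    return LocusData(
        haplotypes=hap,
        positions=np.array(positions, dtype=float),
        pop_labels=pop_labels,
        locus_length=design.locus_length,
    )


def locus_to_vcf(locus: LocusData, out, contig: str = "locus") -> None:
    """Write one locus as an uncompressed phased VCF (1-based positions)."""
    h = locus.haplotypes
    n_dip = h.shape[0] // 2
    names = [f"tsk_{i}" for i in range(n_dip)]
    own = isinstance(out, str)
    fh = open(out, "w") if own else out
    try:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={int(locus.locus_length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        for j in range(locus.n_sites):
            pos = int(np.floor(locus.positions[j])) + 1
            gts = "\t".join(
                f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(n_dip)
            )
            fh.write(f"{contig}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
    finally:
        if own:
            fh.close()
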