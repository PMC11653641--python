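"""Synthetic training and test data: source patches projected to the scalp.

A sample is built by (i) growing a contiguous patch of cortical regions
around a random center, (ii) assigning one or two neural-mass waveforms to
the patch (the whole patch shares one trace, or a center group and a
neighbor group carry different traces to emulate phase differences and
dynamic changes after local propagation), (iii) projecting the region
waveforms through the lead field, (iv) adding sensor white noise at a
controlled SNR and (v) max-abs scaling both the source and the sensor
matrices to [-1, 1].
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import nmm
from .head_model import LeadField, SourceSpace, project_to_sensors

__all__ = [
    "SourcePatch",
    "TrainingSample",
    "DatasetConfig",
    "DatasetManifest",
    "Dataset",
    "grow_patch",
    "partition_patch",
    "add_noise_snr",
    "render_sample",
    "generate_dataset",
    "build_test_sets",
    "load_dataset",
]


@dataclass
class SourcePatch:
    """A contiguous set of active regions with its dynamics assignment."""

    center_region: int
    member_regions: tuple
    center_group: tuple
    neighbor_group: tuple
    dynamics: dict  # group name -> (NMMParams, seed)

    def __post_init__(self) -> None:
        members = set(self.member_regions)
        cg, ng = set(self.center_group), set(self.neighbor_group)
        if cg | ng != members or cg & ng:
            raise ValueError("center/neighbor groups must partition the patch")
        if self.center_region not in cg:
            raise ValueError("center_region must belong to the center group")

    @property
    def size(self) -> int:
        return len(self.member_regions)


@dataclass
class TrainingSample:
    source: np.ndarray  # regions x time, max-abs normalized
    sensors: np.ndarray  # channels x time, max-abs normalized
    patch: SourcePatch
    snr_db: float
    sample_rate: float

    @property
    def time_points(self) -> int:
        return self.source.shape[1]


def grow_patch(
    space: SourceSpace, center_region: int, size: int, seed=0
) -> tuple:
    """Region-grow a connected patch of exactly ``size`` regions.

    Starting from the center, a uniformly chosen region adjacent to the
    current set is added until the requested size is reached.
    """
    if not 1 <= size <= space.region_count:
        raise ValueError("size must be in [1, region_count]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    members = {int(center_region)}
    frontier = set(map(int, space.neighbors(center_region)))
    while len(members) < size:
        frontier -= members
        if not frontier:
            raise ValueError(
                f"patch of size {size} unreachable from region {center_region}"
            )
        pick = int(rng.choice(sorted(frontier)))
        members.add(pick)
        frontier |= set(map(int, space.neighbors(pick)))
    return tuple(sorted(members))


def partition_patch(
    space: SourceSpace, patch: tuple, center_region: int, center_size: int, seed=0
) -> tuple:
    """Split a patch into a grown center group and the remaining neighbors."""
    members = set(patch)
    if center_region not in members:
        raise ValueError("center_region must be part of the patch")
    if not 1 <= center_size <= len(members):
        raise ValueError("center_size must be in [1, len(patch)]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    group = {int(center_region)}
    frontier = set(map(int, space.neighbors(center_region))) & members
    while len(group) < center_size:
        frontier -= group
        if not frontier:
            raise ValueError("center group growth stuck inside the patch")
        pick = int(rng.choice(sorted(frontier)))
        group.add(pick)
        frontier |= set(map(int, space.neighbors(pick))) & members
    center_group = tuple(sorted(group))
    neighbor_group = tuple(sorted(members - group))
    return center_group, neighbor_group


def add_noise_snr(clean: np.ndarray, snr_db: float, seed=0) -> np.ndarray:
    """Add white Gaussian sensor noise at the requested matrix-wide SNR (dB)."""
    clean = np.asarray(clean, dtype=float)
    p_signal = float(np.mean(clean**2))
    if p_signal == 0:
        raise ValueError("cannot set an SNR on an all-zero signal")
    if np.isinf(snr_db):
        return clean.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal(clean.shape)
    scale = np.sqrt(p_signal / (np.mean(noise**2) * 10.0 ** (snr_db / 10.0)))
    return clean + scale * noise


def _group_traces(patch: SourcePatch, time_points, sample_rate, traces=None):
    """Simulate (or accept precomputed) one trace per dynamics group."""
    groups = [g for g in ("center", "neighbor") if patch.dynamics.get(g)]
    out = {}
    for gname in groups:
        params, seed = patch.dynamics[gname]
        if traces is not None and gname in traces:
            tr = np.asarray(traces[gname], dtype=float)
        else:
            tr = nmm.simulate_nmm(
                params, duration=time_points / sample_rate,
                sample_rate=sample_rate, seed=seed,
            ).values
        if tr.size < time_points:
            raise ValueError(
                f"trace of {tr.size} samples shorter than time_points={time_points}"
            )
        out[gname] = tr[:time_points]
    return out


def render_sample(
    patch: SourcePatch,
    lf: LeadField,
    time_points: int = 500,
    snr_db: float = 10.0,
    seed=0,
    sample_rate: float = 500.0,
    traces: dict | None = None,
) -> TrainingSample:
    """Render one source/sensor pair from a patch and its dynamics.

    Regions of a group share one waveform; inactive regions are exactly
    zero before normalization.  ``traces`` can supply precomputed group
    waveforms (used by the batched dataset generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    group_traces = _group_traces(patch, time_points, sample_rate, traces)
    source = np.zeros((lf.n_regions, time_points))
    for gname, regions in (("center", patch.center_group),
                           ("neighbor", patch.neighbor_group)):
        if not regions:
            continue
        gkey = gname if gname in group_traces else "center"
        source[list(regions)] = group_traces[gkey]
    clean = project_to_sensors(source, lf)
    sensors = add_noise_snr(clean, snr_db, rng)
    source = source / np.max(np.abs(source))
    sensors = sensors / np.max(np.abs(sensors))
    return TrainingSample(source, sensors, patch, float(snr_db), sample_rate)


@dataclass(frozen=True)
class DatasetConfig:
    """Generator configuration; the sample count is the exact product
    ``n_centers * variants_per_center * len(snr_levels)``."""

    n_centers: int = 100
    variants_per_center: int = 3
    snr_levels: tuple = (5.0, 10.0, 15.0, 20.0)
    time_points: int = 500
    sample_rate: float = 500.0
    patch_size_range: tuple = (2, 10)
    two_dynamics_fraction: float = 0.5
    split: str = "train"
    shard_size: int = 512

    @property
    def n_samples(self) -> int:
        return self.n_centers * self.variants_per_center * len(self.snr_levels)


@dataclass
class DatasetManifest:
    n_samples: int
    snr_levels: tuple
    config: dict
    seed: int
    shards: list = field(default_factory=list)
    config_hash: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


@dataclass
class Dataset:
    """In-memory dataset: stacked sensor/source arrays plus patch metadata."""

    sensors: np.ndarray  # (n, channels, T) float32
    sources: np.ndarray  # (n, regions, T) float32
    patches: list  # one SourcePatch per sample
    snr_db: np.ndarray
    patch_ids: np.ndarray  # grouping key for leakage-free splits
    manifest: DatasetManifest

    def __len__(self) -> int:
        return self.sensors.shape[0]


def _config_hash(cfg: DatasetConfig, seed: int) -> str:
    payload = json.dumps([dataclasses.asdict(cfg), seed], sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _draw_patches(space, bank_entries, cfg, rng):
    """Patch layouts and dynamics assignments for one dataset."""
    patches = []
    lo, hi = cfg.patch_size_range
    hi = min(hi, space.region_count)
    for _ in range(cfg.n_centers):
        center = int(rng.integers(space.region_count))
        for _ in range(cfg.variants_per_center):
            size = int(rng.integers(lo, hi + 1))
            members = grow_patch(space, center, size, rng)
            two = size > 1 and rng.random() < cfg.two_dynamics_fraction
            e1 = bank_entries[int(rng.integers(len(bank_entries)))]
            dyn = {"center": (e1.params, int(rng.integers(2**31)))}
            if two:
                csize = int(rng.integers(1, size))
                cg, ng = partition_patch(space, members, center, csize, rng)
                e2 = bank_entries[int(rng.integers(len(bank_entries)))]
                dyn["neighbor"] = (e2.params, int(rng.integers(2**31)))
            else:
                cg, ng = members, ()
            patches.append(SourcePatch(center, members, cg, ng, dyn))
    return patches


def _render_block(patches_snr, lf, cfg, rng):
    """Render samples for (patch, snr) pairs with batched trace simulation."""
    jobs = []  # (sample index, group name, params, seed)
    for i, (patch, _snr) in enumerate(patches_snr):
        for gname in ("center", "neighbor"):
            if patch.dynamics.get(gname):
                params, seed = patch.dynamics[gname]
                jobs.append((i, gname, params, seed))
    traces, _ = nmm.simulate_nmm_batch(
        [j[2] for j in jobs],
        duration=cfg.time_points / cfg.sample_rate,
        sample_rate=cfg.sample_rate,
        seeds=[j[3] for j in jobs],
    )
    per_sample: list = [dict() for _ in patches_snr]
    for (i, gname, _p, _s), tr in zip(jobs, traces):
        per_sample[i][gname] = tr
    samples = []
    for (patch, snr), tr in zip(patches_snr, per_sample):
        s = render_sample(patch, lf, cfg.time_points, snr, rng,
                          cfg.sample_rate, traces=tr)
        # keep large datasets compact while accumulating
        s.source = s.source.astype(np.float32)
        s.sensors = s.sensors.astype(np.float32)
        samples.append(s)
    return samples


def _assemble(samples, patches_snr, patch_ids, cfg, seed, out_dir=None):
    sensors = np.stack([s.sensors for s in samples]).astype(np.float32)
    sources = np.stack([s.source for s in samples]).astype(np.float32)
    snrs = np.array([s.snr_db for s in samples])
    manifest = DatasetManifest(
        n_samples=len(samples),
        snr_levels=tuple(cfg.snr_levels),
        config=dataclasses.asdict(cfg),
        seed=seed,
        config_hash=_config_hash(cfg, seed),
    )
    ds = Dataset(sensors, sources, [p for p, _ in patches_snr], snrs,
                 np.asarray(patch_ids), manifest)
    if out_dir is not None:
        save_dataset(ds, out_dir)
    return ds


def generate_dataset(
    space: SourceSpace,
    lf: LeadField,
    bank: nmm.ParameterBank,
    config: DatasetConfig = DatasetConfig(),
    seed: int = 0,
    out_dir=None,
) -> Dataset:
    """Generate the full (centers x variants x SNR levels) sample grid.

    Fully seeded and deterministic; when ``out_dir`` is given the samples
    are also written as sharded HDF5 with a JSON manifest (regeneration
    with the same config and seed skips shards already on disk).
    """
    entries = bank.subset(config.split) or bank.entries
    if not entries:
        raise ValueError("parameter bank has no entries for the requested split")
    rng = np.random.default_rng(seed)
    patches = _draw_patches(space, entries, config, rng)
    patches_snr = [(p, snr) for p in patches for snr in config.snr_levels]
    patch_ids = [i for i in range(len(patches)) for _ in config.snr_levels]
    samples = []
    for lo in range(0, len(patches_snr), config.shard_size):
        hi = min(lo + config.shard_size, len(patches_snr))
        samples.extend(_render_block(patches_snr[lo:hi], lf, config, rng))
    return _assemble(samples, patches_snr, patch_ids, config, seed, out_dir)


def build_test_sets(
    space: SourceSpace,
    lf: LeadField,
    bank: nmm.ParameterBank,
    config: DatasetConfig,
    seed: int = 0,
):
    """The two evaluation datasets.

    Dataset 1: the whole patch shares one waveform whose regime switches
    to a different ictal type at a uniformly random time point (state
    carried over, continuous trace).  Dataset 2: two dynamics groups per
    patch, like the training distribution.  Both span the configured SNR
    levels; parameters are drawn from the bank's test split.
    """
    entries = bank.subset("test") or bank.entries
    if not entries:
        raise ValueError("parameter bank test split is empty")
    rng = np.random.default_rng(seed)

    # dataset 1: single dynamics with a regime switch
    cfg1 = dataclasses.replace(config, two_dynamics_fraction=0.0)
    patches1 = _draw_patches(space, entries, cfg1, rng)
    pre, post, switch_times, seeds = [], [], [], []
    labels_pre, labels_post = [], []
    duration = cfg1.time_points / cfg1.sample_rate
    by_label: dict = {}
    for e in entries:
        by_label.setdefault(e.label.label, []).append(e)
    for p in patches1:
        params1, s1 = p.dynamics["center"]
        lab1 = _label_of(entries, params1)
        other_labels = [l for l in by_label if l != lab1]
        lab2 = int(rng.choice(other_labels)) if other_labels else lab1
        e2 = by_label[lab2][int(rng.integers(len(by_label[lab2])))]
        pre.append(params1)
        post.append(e2.params)
        seeds.append(s1)
        switch_times.append(float(rng.uniform(0.2, 0.8) * duration))
        labels_pre.append(lab1)
        labels_post.append(lab2)
    traces, _ = nmm.simulate_nmm_switch(
        pre, post, switch_times, duration=duration,
        sample_rate=cfg1.sample_rate, seeds=seeds,
    )
    samples1, patches_snr1, pid1 = [], [], []
    for i, p in enumerate(patches1):
        for snr in cfg1.snr_levels:
            s = render_sample(p, lf, cfg1.time_points, snr, rng,
                              cfg1.sample_rate, traces={"center": traces[i]})
            samples1.append(s)
            patches_snr1.append((p, snr))
            pid1.append(i)
    ds1 = _assemble(samples1, patches_snr1, pid1, cfg1, seed)
    ds1.manifest.config["kind"] = "regime-switch"
    ds1.manifest.config["switch_labels"] = list(zip(labels_pre, labels_post))
    ds1.manifest.config["switch_times"] = switch_times

    # dataset 2: two dynamics per patch
    cfg2 = dataclasses.replace(config, two_dynamics_fraction=1.0)
    rng2 = np.random.default_rng(seed + 1)
    patches2 = _draw_patches(space, entries, cfg2, rng2)
    patches_snr2 = [(p, snr) for p in patches2 for snr in cfg2.snr_levels]
    pid2 = [i for i in range(len(patches2)) for _ in cfg2.snr_levels]
    samples2 = []
    for lo in range(0, len(patches_snr2), cfg2.shard_size):
        hi = min(lo + cfg2.shard_size, len(patches_snr2))
        samples2.extend(_render_block(patches_snr2[lo:hi], lf, cfg2, rng2))
    ds2 = _assemble(samples2, patches_snr2, pid2, cfg2, seed + 1)
    ds2.manifest.config["kind"] = "two-dynamics"
    return ds1, ds2


def _label_of(entries, params) -> int:
    for e in entries:
        if e.params == params:
            return e.label.label
    return -1


def save_dataset(ds: Dataset, out_dir) -> None:
    import h5py

    os.makedirs(out_dir, exist_ok=True)
    shard = ds.manifest.config.get("shard_size", 512)
    shards = []
    for k, lo in enumerate(range(0, len(ds), shard)):
        hi = min(lo + shard, len(ds))
        name = f"shard_{k:04d}.h5"
        path = os.path.join(out_dir, name)
        shards.append(name)
        if os.path.exists(path):
            continue  # resumable: shard already written for this manifest
        with h5py.File(path, "w") as fh:
            fh.create_dataset("sensors", data=ds.sensors[lo:hi])
            fh.create_dataset("sources", data=ds.sources[lo:hi])
            fh.create_dataset("snr_db", data=ds.snr_db[lo:hi])
            fh.create_dataset("patch_ids", data=ds.patch_ids[lo:hi])
            members = [list(p.member_regions) for p in ds.patches[lo:hi]]
            fh.create_dataset(
                "patch_members_json",
                data=np.array([json.dumps(m) for m in members], dtype="S"),
            )
    ds.manifest.shards = shards
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        fh.write(ds.manifest.to_json())


def load_dataset(out_dir) -> Dataset:
    import h5py

    with open(os.path.join(out_dir, "manifest.json")) as fh:
        m = json.load(fh)
    manifest = DatasetManifest(
        m["n_samples"], tuple(m["snr_levels"]), m["config"], m["seed"],
        m["shards"], m["config_hash"],
    )
    sensors, sources, snrs, pids, patches = [], [], [], [], []
    for name in manifest.shards:
        with h5py.File(os.path.join(out_dir, name), "r") as fh:
            sensors.append(fh["sensors"][()])
            sources.append(fh["sources"][()])
            snrs.append(fh["snr_db"][()])
            pids.append(fh["patch_ids"][()])
            for blob in fh["patch_members_json"][()]:
                members = tuple(json.loads(blob.decode()))
                patches.append(
                    SourcePatch(members[0], members, members, (), {"center": (None, 0)})
                )
    return Dataset(
        np.concatenate(sensors), np.concatenate(sources),
        patches, np.concatenate(snrs), np.concatenate(pids), manifest,
    )
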