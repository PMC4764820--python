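"""Synthetic cohort generator with planted deletions and truth labels.

Generates, from one seed, everything the pipeline consumes: an STS catalog,
a raw samples x STSs depth matrix, haplogroup marker genotypes, cohort
metadata and per-pair truth labels. The generative model mirrors targeted
capture: depth at (sample i, STS j) is negative-binomial noise around

    base_depth * sample_scale_i * efficiency_j * copy_mult_j * state_ij

where ``state_ij`` is 1 for present sites, ``residual_depth_fraction`` for
truly deleted sites (non-specific capture keeps depth above zero), and 0.5
for multi-copy sites that lost one of two copies (which the caller is *not*
expected to flag).

Planted deletion architecture:

* a recurrent 3-STS block in the AZFc-like region, carried by every
  haplogroup-N sample (and only those), emulating a founder deletion;
* rare long multi-STS intervals in cases;
* scattered single-STS deletions in both groups, with a higher rate in
  cases;
* two control STSs (``sY84``, ``sY86``) that are never deleted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from stsdel.catalog import STSCatalog, STSRecord, write_catalog
from stsdel.errors import ValidationError
from stsdel.features import FeatureMatrix
from stsdel.haplogroup import MISSING, HaplogroupTree, default_tree
from stsdel.qc import DepthMatrix
from stsdel.svm import TrainingSet

CONTROL_STS = ("sY84", "sY86")
FOUNDER_BLOCK = ("DYF155S1", "RH102047", "sY1191")

DEFAULT_HAPLOGROUP_FREQS = {
    "O3a": 0.45,
    "O2a": 0.10,
    "O2": 0.04,
    "O2b": 0.03,
    "O1a2": 0.03,
    "C": 0.12,
    "N": 0.07,
    "Q": 0.06,
    "D": 0.04,
    "J": 0.02,
    "R": 0.02,
    "G": 0.01,
    "T": 0.01,
}


@dataclass(frozen=True)
class SimScenario:
    """All knobs of the generative model. ``seed`` is mandatory."""

    seed: int
    n_cases: int = 100
    n_controls: int = 100
    n_sts: int = 300
    chrom: str = "chrY"
    multi_copy_fraction: float = 0.12
    base_depth: float = 38.25
    #: lognormal sigma of per-STS capture efficiency (mean 1)
    efficiency_sd: float = 0.25
    #: lognormal sigma of per-sample depth scale (mean 1)
    sample_scale_sd: float = 0.15
    #: negative binomial size parameter; larger = closer to Poisson. The
    #: default reflects that an STS's *mean* per-base depth averages over
    #: ~100+ reads, so its relative noise is far below a single-count draw.
    nb_dispersion: float = 150.0
    residual_depth_fraction: float = 0.05
    #: probability a multi-copy site lost one of its two copies in a sample
    copy_loss_rate: float = 0.04
    #: fraction of cases carrying one planted long deletion
    case_long_deletion_rate: float = 0.35
    long_deletion_span: tuple[int, int] = (10, 25)
    #: Poisson mean of scattered single-STS deletions per sample
    case_singleton_mean: float = 6.0
    control_singleton_mean: float = 1.5
    haplogroup_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAPLOGROUP_FREQS)
    )
    marker_dropout: float = 0.0
    #: mean gap between consecutive STSs in bp
    mean_gap: int = 20_000
    #: probability of an oversized (> merge window) gap
    big_gap_prob: float = 0.03

    def __post_init__(self) -> None:
        for name in (
            "multi_copy_fraction",
            "residual_depth_fraction",
            "copy_loss_rate",
            "case_long_deletion_rate",
            "marker_dropout",
            "big_gap_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_cases <= 0 or self.n_controls <= 0 or self.n_sts <= 0:
            raise ValidationError("cohort and catalog sizes must be positive")
        if self.n_sts < len(CONTROL_STS) + len(FOUNDER_BLOCK) + 10:
            raise ValidationError("n_sts too small for the planted architecture")
        total = sum(self.haplogroup_freqs.values())
        if not 0.999 <= total <= 1.001:
            raise ValidationError("haplogroup frequencies must sum to 1")
        if self.long_deletion_span[0] < 1 or self.long_deletion_span[1] >= self.n_sts:
            raise ValidationError("infeasible long_deletion_span for this catalog")

    def content_hash(self) -> str:
        payload = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        payload = yaml.safe_load(Path(path).read_text())
        if "long_deletion_span" in payload:
            payload["long_deletion_span"] = tuple(payload["long_deletion_span"])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = dict(self.__dict__)
        payload["long_deletion_span"] = list(self.long_deletion_span)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass
class SimTruth:
    """Planted ground truth for one simulated cohort."""

    #: samples x STSs boolean matrix of true deletion states
    deleted: pd.DataFrame
    #: sample_id -> list of (first_sts_index, last_sts_index) planted runs
    intervals: dict[str, list[tuple[int, int]]]
    #: sample_id -> planted haplogroup
    haplogroups: dict[str, str]

    def deletion_fraction(self) -> float:
        return float(self.deleted.to_numpy().mean())


@dataclass
class SimCohort:
    scenario: SimScenario
    catalog: STSCatalog
    depth: DepthMatrix
    genotypes: pd.DataFrame
    metadata: pd.DataFrame
    truth: SimTruth
    tree: HaplogroupTree


def _simulate_catalog(scenario: SimScenario, rng: np.random.Generator) -> STSCatalog:
    n = scenario.n_sts
    gaps = rng.exponential(scenario.mean_gap, size=n).astype(int) + 500
    big = rng.random(n) < scenario.big_gap_prob
    gaps[big] += 150_000
    lengths = rng.integers(100, 600, size=n)
    starts = np.cumsum(gaps) + 2_650_000
    multi = rng.random(n) < scenario.multi_copy_fraction

    # region blocks along the coordinate axis (index-based, roughly sized)
    bounds = {
        "Yp": int(0.15 * n),
        "other": int(0.40 * n),
        "AZFa": int(0.50 * n),
        "AZFb": int(0.65 * n),
        "AZFc": n,
    }

    def region_of(idx: int) -> str:
        for name, hi in bounds.items():
            if idx < hi:
                return name
        return "AZFc"

    annotations = rng.choice(
        ["coding", "UTR", "intron", "intergenic"], size=n, p=[0.08, 0.05, 0.27, 0.60]
    )

    ids = [f"sts{idx:04d}" for idx in range(n)]
    # control STSs sit in the AZFa-like block; the founder block is a
    # contiguous triplet inside the AZFc-like block
    azfa_lo, azfa_hi = bounds["other"], bounds["AZFa"]
    ids[azfa_lo] = CONTROL_STS[0]
    ids[azfa_lo + 1] = CONTROL_STS[1]
    azfc_lo = bounds["AZFb"]
    founder_at = azfc_lo + 2
    for k, name in enumerate(FOUNDER_BLOCK):
        ids[founder_at + k] = name

    records = []
    for idx in range(n):
        records.append(
            STSRecord(
                sts_id=ids[idx],
                chrom=scenario.chrom,
                start=int(starts[idx]),
                end=int(starts[idx] + lengths[idx]),
                copy_class="multi" if multi[idx] and ids[idx] not in CONTROL_STS else "single",
                region=region_of(idx),
                annotation=str(annotations[idx]),
                gene=f"GENE{idx // 12}" if annotations[idx] != "intergenic" else None,
            )
        )
    return STSCatalog(records)


def _plant_deletions(
    scenario: SimScenario,
    rng: np.random.Generator,
    sample_ids: list[str],
    groups: dict[str, str],
    haplogroups: dict[str, str],
    sts_ids: list[str],
) -> SimTruth:
    n_sts = len(sts_ids)
    idx_of = {t: k for k, t in enumerate(sts_ids)}
    protected = {idx_of[t] for t in CONTROL_STS}
    founder_idx = [idx_of[t] for t in FOUNDER_BLOCK]
    deleted = np.zeros((len(sample_ids), n_sts), dtype=bool)
    intervals: dict[str, list[tuple[int, int]]] = {s: [] for s in sample_ids}

    for i, sample in enumerate(sample_ids):
        if haplogroups[sample] == "N":
            deleted[i, founder_idx] = True
            intervals[sample].append((min(founder_idx), max(founder_idx)))
        if groups[sample] == "case" and rng.random() < scenario.case_long_deletion_rate:
            span = int(rng.integers(*scenario.long_deletion_span))
            start = int(rng.integers(0, n_sts - span))
            run = [k for k in range(start, start + span) if k not in protected]
            if run:
                deleted[i, run] = True
                intervals[sample].append((min(run), max(run)))
        mean = (
            scenario.case_singleton_mean
            if groups[sample] == "case"
            else scenario.control_singleton_mean
        )
        n_singletons = int(rng.poisson(mean))
        for k in rng.integers(0, n_sts, size=n_singletons):
            if int(k) not in protected:
                deleted[i, int(k)] = True

    frame = pd.DataFrame(deleted, index=sample_ids, columns=sts_ids)
    return SimTruth(deleted=frame, intervals=intervals, haplogroups=dict(haplogroups))


def _simulate_depth(
    scenario: SimScenario,
    rng: np.random.Generator,
    truth: SimTruth,
    catalog: STSCatalog,
) -> DepthMatrix:
    sample_ids = list(truth.deleted.index)
    sts_ids = list(truth.deleted.columns)
    n_i, n_j = len(sample_ids), len(sts_ids)
    efficiency = rng.lognormal(0.0, scenario.efficiency_sd, size=n_j)
    efficiency /= efficiency.mean()
    scale = rng.lognormal(0.0, scenario.sample_scale_sd, size=n_i)
    scale /= scale.mean()
    copy_mult = np.array(
        [2.0 if catalog[t].is_multi_copy() else 1.0 for t in sts_ids]
    )
    state = np.where(truth.deleted.to_numpy(), scenario.residual_depth_fraction, 1.0)
    multi = copy_mult == 2.0
    copy_lost = (rng.random((n_i, n_j)) < scenario.copy_loss_rate) & multi[None, :]
    state = np.where(copy_lost & (state == 1.0), 0.5, state)

    mean = scenario.base_depth * scale[:, None] * efficiency[None, :] * copy_mult[None, :] * state
    mean = np.maximum(mean, 1e-9)
    r = scenario.nb_dispersion
    p = r / (r + mean)
    depth = rng.negative_binomial(r, p).astype(float)
    frame = pd.DataFrame(depth, index=sample_ids, columns=sts_ids)
    frame.index.name = "sample_id"
    return DepthMatrix(frame, normalized=False)


def _simulate_genotypes(
    scenario: SimScenario,
    rng: np.random.Generator,
    tree: HaplogroupTree,
    haplogroups: dict[str, str],
) -> pd.DataFrame:
    marker_alleles = {
        m.marker_id: (m.ancestral, m.derived)
        for marks in tree.markers.values()
        for m in marks
    }
    marker_ids = sorted(marker_alleles)
    rows = {}
    for sample, hap in haplogroups.items():
        path_markers = {
            m.marker_id
            for node in tree.path(hap)
            for m in tree.markers.get(node, ())
        }
        calls = {}
        for mid in marker_ids:
            anc, der = marker_alleles[mid]
            allele = der if mid in path_markers else anc
            if scenario.marker_dropout and rng.random() < scenario.marker_dropout:
                allele = MISSING
            calls[mid] = allele
        rows[sample] = calls
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=marker_ids)
    frame.index.name = "sample_id"
    return frame


def simulate_cohort(scenario: SimScenario) -> SimCohort:
    """Generate one complete cohort; identical output for identical scenario."""
    rng = np.random.default_rng(scenario.seed)
    tree = default_tree()
    catalog = _simulate_catalog(scenario, rng)
    sts_ids = catalog.sts_ids

    sample_ids = [f"case{i:04d}" for i in range(scenario.n_cases)] + [
        f"ctrl{i:04d}" for i in range(scenario.n_controls)
    ]
    groups = {
        s: ("case" if s.startswith("case") else "control") for s in sample_ids
    }
    haps = list(scenario.haplogroup_freqs)
    probs = np.array([scenario.haplogroup_freqs[h] for h in haps])
    probs = probs / probs.sum()
    assigned = rng.choice(haps, size=len(sample_ids), p=probs)
    haplogroups = dict(zip(sample_ids, (str(h) for h in assigned)))

    truth = _plant_deletions(scenario, rng, sample_ids, groups, haplogroups, sts_ids)
    depth = _simulate_depth(scenario, rng, truth, catalog)
    genotypes = _simulate_genotypes(scenario, rng, tree, haplogroups)
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "group": [groups[s] for s in sample_ids]}
    )
    return SimCohort(
        scenario=scenario,
        catalog=catalog,
        depth=depth,
        genotypes=genotypes,
        metadata=metadata,
        truth=truth,
        tree=tree,
    )


def null_scenario(seed: int, **overrides) -> SimScenario:
    """A scenario with no planted deletions (degenerate null)."""
    base = dict(
        seed=seed,
        case_long_deletion_rate=0.0,
        case_singleton_mean=0.0,
        control_singleton_mean=0.0,
        copy_loss_rate=0.0,
        haplogroup_freqs=_freqs_without_n(),
    )
    base.update(overrides)
    return SimScenario(**base)


def _freqs_without_n() -> dict[str, float]:
    freqs = {h: f for h, f in DEFAULT_HAPLOGROUP_FREQS.items() if h != "N"}
    total = sum(freqs.values())
    return {h: f / total for h, f in freqs.items()}


def make_training_subset(
    truth: SimTruth,
    features: FeatureMatrix,
    n_events: int = 134,
    n_samples: int = 26,
    seed: int = 0,
    deleted_fraction: float | None = None,
) -> TrainingSet:
    """Draw labeled training events from at most ``n_samples`` samples.

    Samples carrying deletions are preferred so both classes are present.
    ``deleted_fraction`` defaults to the observed prevalence among the chosen
    samples' qualified pairs, clamped so each class gets at least 10 events
    (or 1 for tiny draws).
    """
    if n_events <= 0:
        raise ValidationError("n_events must be positive")
    rng = np.random.default_rng(seed)
    feat = features.table.set_index(["sample_id", "sts_id"])

    truth_long = truth.deleted.stack()
    truth_long.index.names = ["sample_id", "sts_id"]
    truth_long = truth_long[truth_long.index.isin(feat.index)]

    # choose samples by greedy coverage of distinct deleted STSs so every
    # deletion flavour (rare long runs, recurrent founder blocks, singletons)
    # contributes labeled events; ties and the remainder go to high burden
    per_sample_del = truth_long.groupby(level="sample_id").sum().sort_values(ascending=False)
    deleted_by_sample = {
        s: set(g.index.get_level_values("sts_id"))
        for s, g in truth_long[truth_long].groupby(level="sample_id")
    }
    chosen: list[str] = []
    covered: set[str] = set()
    candidates = dict(deleted_by_sample)
    while candidates and len(chosen) < n_samples:
        best = max(
            candidates,
            key=lambda s: (len(candidates[s] - covered), per_sample_del.get(s, 0), s),
        )
        if not candidates[best] - covered:
            break
        chosen.append(best)
        covered |= candidates.pop(best)
    for s in per_sample_del.index:
        if len(chosen) >= n_samples:
            break
        if s not in chosen:
            chosen.append(s)
    pool = truth_long[truth_long.index.get_level_values("sample_id").isin(chosen)]
    deleted_pool = pool[pool].index.to_list()
    clean_pool = pool[~pool].index.to_list()
    if len(pool) < n_events:
        raise ValidationError(
            f"requested {n_events} events but only {len(pool)} qualified pairs "
            f"available in {n_samples} samples"
        )
    if not deleted_pool or not clean_pool:
        raise ValidationError("training pool must contain both classes")

    if deleted_fraction is None:
        # observed prevalence, floored at a quarter of the draw: a handful of
        # deleted events cannot span the deleted feature range, and the
        # labeled set is meant to cover it
        deleted_fraction = max(len(deleted_pool) / len(pool), 0.25)
    floor = min(10, n_events // 4) or 1
    n_del = int(round(n_events * deleted_fraction))
    n_del = max(floor, min(n_del, n_events - floor, len(deleted_pool)))
    n_clean = n_events - n_del
    if n_clean > len(clean_pool):
        raise ValidationError("not enough non-deleted pairs in the training pool")

    # spread both draws across the f1 range (decile strata) so the classifier
    # sees the full spectrum of depth behaviour — extreme and moderate
    # dropouts among deleted events, and both depth tails among clean ones —
    # not just the bulk around f2 = f3 = 1
    pick_del = _stratified_draw(feat, deleted_pool, n_del, rng)
    pick_clean = _stratified_draw(feat, clean_pool, n_clean, rng)
    index = pick_del + pick_clean
    table = feat.loc[index].reset_index()
    table["deleted"] = [True] * n_del + [False] * n_clean
    return TrainingSet(table)


def _stratified_draw(feat: pd.DataFrame, pool: list, n: int, rng) -> list:
    """Draw ``n`` pairs from ``pool`` spread over f1 decile strata, preferring
    events from STSs not yet represented in the draw."""
    f1 = feat.loc[pool, "f1"].to_numpy()
    order = np.argsort(f1)
    picks: list[int] = []
    seen_sts: set[str] = set()
    quota = n
    if n >= 4:  # anchor the extremes so the draw always spans the full range
        for k in (int(order[0]), int(order[-1])):
            picks.append(k)
            seen_sts.add(pool[k][1])
            quota -= 1
        order = order[1:-1]
    strata = np.array_split(order, max(1, min(10, quota)))
    for s, stratum in enumerate(strata):
        want = min(quota // (len(strata) - s), len(stratum))
        shuffled = list(rng.permutation(stratum))
        fresh = [k for k in shuffled if pool[int(k)][1] not in seen_sts]
        rest = [k for k in shuffled if k not in set(map(int, fresh))]
        for k in (fresh + rest)[:want]:
            picks.append(int(k))
            seen_sts.add(pool[int(k)][1])
        quota -= want
    if quota:  # top up uniformly if strata ran short
        remaining = np.setdiff1d(np.arange(len(pool)), picks)
        picks.extend(int(k) for k in rng.choice(remaining, quota, replace=False))
    return [pool[k] for k in picks]


def write_workspace(cohort: SimCohort, outdir: str | Path) -> dict[str, Path]:
    """Materialize every artifact of a simulated cohort as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": outdir / "catalog.tsv",
        "depth": outdir / "depth.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
        "tree": outdir / "tree.yaml",
        "scenario": outdir / "scenario.yaml",
    }
    write_catalog(cohort.catalog, paths["catalog"])
    cohort.depth.to_tsv(paths["depth"])
    cohort.genotypes.to_csv(paths["genotypes"], sep="\t")
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    truth_out = cohort.truth.deleted.astype(int)
    truth_out.index.name = "sample_id"
    truth_out.to_csv(paths["truth"], sep="\t")
    cohort.tree.to_yaml(paths["tree"])
    cohort.scenario.to_yaml(paths["scenario"])
    provenance = outdir / "PROVENANCE.txt"
    provenance.write_text(
        f"scenario_hash\t{cohort.scenario.content_hash()}\nseed\t{cohort.scenario.seed}\n"
    )
    paths["provenance"] = provenance
    return paths
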