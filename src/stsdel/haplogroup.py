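"""Y-haplogroup assignment from marker genotypes and association tests.

A haplogroup tree is a rooted hierarchy of named nodes; each non-root node
carries defining markers with an ancestral and a derived allele. Assignment
descends from the root: a child is entered iff all its defining markers are
called and derived. If descent stops because a candidate child has missing
marker calls (rather than being definitively excluded by an ancestral call),
the sample is left unassigned, so dropout can never yield a wrong lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from scipy.stats import binomtest, fisher_exact

from stsdel.errors import ValidationError
from stsdel.svm import DELETED, CallMatrix

MISSING = "."
ALLELES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class Marker:
    marker_id: str
    ancestral: str
    derived: str

    def __post_init__(self) -> None:
        if self.ancestral not in ALLELES or self.derived not in ALLELES:
            raise ValidationError(
                f"marker {self.marker_id!r}: alleles must be one of {sorted(ALLELES)}"
            )
        if self.ancestral == self.derived:
            raise ValidationError(
                f"marker {self.marker_id!r}: ancestral equals derived allele"
            )


@dataclass
class HaplogroupTree:
    """Rooted tree of haplogroup nodes with defining markers."""

    #: node name -> parent name (root maps to None)
    parents: dict[str, str | None]
    #: node name -> defining markers (root has none)
    markers: dict[str, tuple[Marker, ...]]

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {roots}")
        self._root = roots[0]
        for node, parent in self.parents.items():
            if parent is not None and parent not in self.parents:
                raise ValidationError(f"node {node!r} has unknown parent {parent!r}")
        # acyclicity: every node must reach the root
        for node in self.parents:
            seen = set()
            cur: str | None = node
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"cycle in tree at node {cur!r}")
                seen.add(cur)
                cur = self.parents[cur]
        for node, marks in self.markers.items():
            ids = [m.marker_id for m in marks]
            if len(ids) != len(set(ids)):
                raise ValidationError(f"node {node!r} repeats a marker id")

    @property
    def root(self) -> str:
        return self._root

    def children(self, node: str) -> list[str]:
        return sorted(n for n, p in self.parents.items() if p == node)

    def path(self, node: str) -> list[str]:
        out = []
        cur: str | None = node
        while cur is not None:
            out.append(cur)
            cur = self.parents[cur]
        return out[::-1]

    def all_marker_ids(self) -> list[str]:
        return [m.marker_id for marks in self.markers.values() for m in marks]

    def is_ancestor_or_equal(self, a: str, b: str) -> bool:
        """True if ``a`` lies on the root-to-``b`` path."""
        return a in self.path(b)

    @classmethod
    def from_dict(cls, payload: dict) -> "HaplogroupTree":
        parents: dict[str, str | None] = {}
        markers: dict[str, tuple[Marker, ...]] = {}
        for node in payload["nodes"]:
            name = node["name"]
            parents[name] = node.get("parent")
            markers[name] = tuple(
                Marker(m["id"], m["ancestral"], m["derived"])
                for m in node.get("markers", [])
            )
        return cls(parents, markers)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HaplogroupTree":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        nodes = [
            {
                "name": name,
                "parent": parent,
                "markers": [
                    {"id": m.marker_id, "ancestral": m.ancestral, "derived": m.derived}
                    for m in self.markers.get(name, ())
                ],
            }
            for name, parent in self.parents.items()
        ]
        Path(path).write_text(yaml.safe_dump({"nodes": nodes}, sort_keys=False))


def default_tree() -> HaplogroupTree:
    """The shipped 9-major-haplogroup tree with O sub-lineages.

    Marker ids are editable placeholders standing in for curated SNP panels;
    swap the YAML export for a curated tree in production use.
    """
    spec: list[tuple[str, str | None, list[tuple[str, str, str]]]] = [
        ("Y", None, []),
        ("C", "Y", [("M130", "C", "T")]),
        ("D", "Y", [("M174", "T", "C")]),
        ("G", "Y", [("M201", "G", "T")]),
        ("J", "Y", [("M304", "A", "C")]),
        ("N", "Y", [("M231", "G", "A")]),
        ("Q", "Y", [("M242", "C", "T")]),
        ("R", "Y", [("M207", "A", "G")]),
        ("T", "Y", [("M70", "A", "C")]),
        ("O", "Y", [("M175", "T", "C")]),
        ("O1a2", "O", [("M110", "T", "C")]),
        ("O2", "O", [("P31", "G", "A")]),
        ("O2a", "O2", [("M95", "C", "T")]),
        ("O2b", "O2", [("SRY465", "C", "T")]),
        ("O3a", "O", [("M324", "G", "A")]),
    ]
    parents = {name: parent for name, parent, _ in spec}
    markers = {
        name: tuple(Marker(mid, anc, der) for mid, anc, der in marks)
        for name, _, marks in spec
    }
    return HaplogroupTree(parents, markers)


@dataclass
class HaplogroupAssignment:
    sample_id: str
    haplogroup: str | None  # None = unassigned
    path: tuple[str, ...] = field(default_factory=tuple)
    reason: str = ""

    @property
    def assigned(self) -> bool:
        return self.haplogroup is not None


def assign(
    tree: HaplogroupTree, genotypes: dict[str, str] | pd.Series, sample_id: str = "sample"
) -> HaplogroupAssignment:
    """Assign one sample to the deepest haplogroup its derived markers support.

    ``genotypes`` maps marker id -> allele call ('.' = missing). Every marker
    in the tree must be present in the table schema (missing *calls* are
    allowed, missing *columns* are a configuration error).
    """
    if isinstance(genotypes, pd.Series):
        genotypes = genotypes.to_dict()
    schema = set(genotypes)
    absent = set(tree.all_marker_ids()) - schema
    if absent:
        raise ValidationError(
            f"markers required by the tree are absent from the genotype table: "
            f"{sorted(absent)[:5]}"
        )

    node = tree.root
    while True:
        entered = None
        uncertain = False
        for child in tree.children(node):
            status = _node_status(tree, child, genotypes)
            if status == "derived":
                entered = child
                break
            if status == "missing":
                uncertain = True
        if entered is None:
            if uncertain:
                return HaplogroupAssignment(
                    sample_id, None, tuple(tree.path(node)),
                    reason="missing marker call on descent frontier",
                )
            break
        node = entered

    if node == tree.root:
        return HaplogroupAssignment(
            sample_id, None, (tree.root,), reason="no derived lineage markers"
        )
    return HaplogroupAssignment(sample_id, node, tuple(tree.path(node)))


def _node_status(tree: HaplogroupTree, node: str, genotypes: dict[str, str]) -> str:
    """'derived' if all defining markers are called derived, 'excluded' if any
    is called non-derived, else 'missing'."""
    any_missing = False
    for m in tree.markers.get(node, ()):
        call = genotypes.get(m.marker_id, MISSING)
        if call == MISSING or (isinstance(call, float) and pd.isna(call)):
            any_missing = True
        elif call != m.derived:
            return "excluded"
    if any_missing:
        return "missing"
    return "derived"


def assign_all(tree: HaplogroupTree, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Assign every row of a sample x marker genotype table.

    Returns a frame with columns sample_id, haplogroup ('.' if unassigned),
    path.
    """
    rows = []
    for sample_id, row in genotypes.iterrows():
        a = assign(tree, row, sample_id=str(sample_id))
        rows.append(
            {
                "sample_id": str(sample_id),
                "haplogroup": a.haplogroup or MISSING,
                "path": ">".join(a.path),
            }
        )
    return pd.DataFrame(rows)


def haplogroup_association(
    assignments: pd.DataFrame, metadata: pd.DataFrame,
    case_group: str = "case", control_group: str = "control",
) -> pd.DataFrame:
    """Per-haplogroup one-sided Fisher exact test of case/control imbalance.

    For each haplogroup, the 2x2 table is carriers vs non-carriers by group
    among assigned samples; the one-sided tail is taken in the direction of
    the observed deviation (depletion in cases -> lower tail).
    """
    merged = assignments.merge(metadata, on="sample_id", how="inner")
    merged = merged[merged["haplogroup"] != MISSING]
    cases = merged[merged["group"] == case_group]
    controls = merged[merged["group"] == control_group]
    if len(cases) == 0 or len(controls) == 0:
        raise ValidationError("both groups must contain assigned samples")
    n_case, n_ctrl = len(cases), len(controls)
    rows = []
    for hap in sorted(merged["haplogroup"].unique()):
        a = int((cases["haplogroup"] == hap).sum())
        c = int((controls["haplogroup"] == hap).sum())
        table = [[a, n_case - a], [c, n_ctrl - c]]
        side = "less" if a / n_case <= c / n_ctrl else "greater"
        _, p = fisher_exact(table, alternative=side)
        rows.append(
            {
                "haplogroup": hap,
                "case_carriers": a,
                "case_total": n_case,
                "control_carriers": c,
                "control_total": n_ctrl,
                "direction": side,
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def haplogroup_deletion_enrichment(
    calls: CallMatrix, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Per (haplogroup, STS): observed vs expected deletion count.

    Expected = total cohort deletions of the STS x (haplogroup size / cohort
    size); the p-value is a two-sided exact binomial test of the observed
    count against that proportion.
    """
    assigned = assignments[assignments["haplogroup"] != MISSING]
    if assigned.empty:
        raise ValidationError("no assigned samples")
    hap_of = dict(zip(assigned["sample_id"], assigned["haplogroup"]))
    cohort = len(assigned)
    deleted = calls.table[
        (calls.table["state"] == DELETED)
        & calls.table["sample_id"].isin(hap_of)
    ]
    hap_sizes = assigned["haplogroup"].value_counts().to_dict()
    rows = []
    for sts_id, group in deleted.groupby("sts_id", sort=True):
        total = len(group)
        by_hap = group["sample_id"].map(hap_of).value_counts().to_dict()
        for hap in sorted(hap_sizes):
            frac = hap_sizes[hap] / cohort
            observed = int(by_hap.get(hap, 0))
            expected = total * frac
            p = binomtest(observed, total, frac, alternative="two-sided").pvalue
            rows.append(
                {
                    "haplogroup": hap,
                    "sts_id": sts_id,
                    "observed": observed,
                    "expected": expected,
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)
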