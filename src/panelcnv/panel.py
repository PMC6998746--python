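"""Capture-panel model: genes, exons, ~200 bp bins and joined target groups.

The panel is the coordinate backbone of read-depth CNV flagging.  Exons of
the capture design are partitioned into nonoverlapping bins of roughly
200 bp; bins are then joined into *target groups* at several levels
(single bin, exon, sliding multi-exon windows, whole gene) so that large
events — a four-exon deletion, a whole-gene duplication — concentrate
their signal in a single scored unit.

Coordinates are 0-based half-open (BED convention) everywhere internally.
Regions whose read depth is uninterpretable because of highly homologous
pseudogenes (PMS2 and CHEK2 exons 11-15) are masked: masked bins never
contribute to normalization statistics, grouping or flags.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "Target",
    "TargetGroup",
    "Panel",
    "PanelError",
    "load_panel_bed",
    "write_panel_bed",
    "make_bins",
    "make_target_groups",
    "apply_mask",
    "demo_panel",
    "DEFAULT_MASK",
    "DEFAULT_WINDOW_SIZES",
]

#: Pseudogene-confounded exons excluded from copy-number analysis.
DEFAULT_MASK: tuple[tuple[str, tuple[int, int]], ...] = (
    ("PMS2", (11, 15)),
    ("CHEK2", (11, 15)),
)

DEFAULT_WINDOW_SIZES: tuple[int, ...] = (2, 4, 8)

TARGET_KINDS = ("exon", "bin", "promoter", "intronic")
GROUP_LEVELS = ("single_bin", "exon", "multi_exon_window", "whole_gene")


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel definitions."""


@dataclass(frozen=True)
class Target:
    """One genomic interval of the capture design (exon, bin, promoter...)."""

    target_id: str
    gene: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    kind: str = "exon"
    exon_index: int | None = None
    masked: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PanelError(
                f"target {self.target_id}: end ({self.end}) must be > start ({self.start})"
            )
        if self.kind not in TARGET_KINDS:
            raise PanelError(f"target {self.target_id}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TargetGroup:
    """A set of contiguous bins of one gene scored jointly.

    ``level`` is one of single_bin / exon / multi_exon_window / whole_gene;
    multi-exon windows additionally carry their ``window_size``.  The
    ``stratum`` key (level plus window size) is the unit at which Z.adj
    denominators and flagging cutoffs are stratified.
    """

    group_id: str
    gene: str
    member_target_ids: tuple[str, ...]
    level: str
    span: tuple[str, int, int]  # chrom, start, end
    window_size: int | None = None
    first_exon: int | None = None
    last_exon: int | None = None

    def __post_init__(self) -> None:
        if self.level not in GROUP_LEVELS:
            raise PanelError(f"group {self.group_id}: unknown level {self.level!r}")
        if not self.member_target_ids:
            raise PanelError(f"group {self.group_id}: empty membership")

    @property
    def stratum(self) -> str:
        if self.level == "multi_exon_window":
            return f"window{self.window_size}"
        return self.level


@dataclass
class Panel:
    """A capture panel: targets (exons + bins) and scored target groups."""

    name: str
    targets: list[Target] = field(default_factory=list)
    groups: list[TargetGroup] = field(default_factory=list)
    bin_size: int | None = None
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES

    def __post_init__(self) -> None:
        self._validate()

    # -- lookups -----------------------------------------------------------
    def _validate(self) -> None:
        seen: set[str] = set()
        for t in self.targets:
            if t.target_id in seen:
                raise PanelError(f"duplicate target id {t.target_id!r}")
            seen.add(t.target_id)
        gseen: set[str] = set()
        for g in self.groups:
            if g.group_id in gseen:
                raise PanelError(f"duplicate group id {g.group_id!r}")
            gseen.add(g.group_id)
        # bins of one gene must not overlap
        for gene in {t.gene for t in self.targets}:
            bins = sorted(
                (t for t in self.targets if t.gene == gene and t.kind == "bin"),
                key=lambda t: (t.chrom, t.start),
            )
            for a, b in zip(bins, bins[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise PanelError(
                        f"overlapping bins in {gene}: {a.target_id} / {b.target_id}"
                    )

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for t in self.targets:
            if t.gene not in out:
                out.append(t.gene)
        return out

    @property
    def target_by_id(self) -> dict[str, Target]:
        return {t.target_id: t for t in self.targets}

    @property
    def group_by_id(self) -> dict[str, TargetGroup]:
        return {g.group_id: g for g in self.groups}

    def exons(self, gene: str | None = None) -> list[Target]:
        out = [t for t in self.targets if t.kind == "exon"]
        if gene is not None:
            out = [t for t in out if t.gene == gene]
        return sorted(out, key=lambda t: (t.chrom, t.start))

    def bins(self, gene: str | None = None, include_masked: bool = True) -> list[Target]:
        out = [t for t in self.targets if t.kind == "bin"]
        if gene is not None:
            out = [t for t in out if t.gene == gene]
        if not include_masked:
            out = [t for t in out if not t.masked]
        return sorted(out, key=lambda t: (t.chrom, t.start))

    def bin_ids(self, include_masked: bool = True) -> list[str]:
        return [t.target_id for t in self.bins(include_masked=include_masked)]

    def fingerprint(self) -> str:
        """Stable digest of the panel geometry (targets, masks, groups)."""
        payload = {
            "targets": [
                (t.target_id, t.gene, t.chrom, t.start, t.end, t.kind, t.exon_index, t.masked)
                for t in sorted(self.targets, key=lambda t: t.target_id)
            ],
            "groups": [
                (g.group_id, g.level, g.member_target_ids)
                for g in sorted(self.groups, key=lambda g: g.group_id)
            ],
        }
        blob = json.dumps(payload, separators=(",", ":")).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "bin_size": self.bin_size,
            "window_sizes": list(self.window_sizes),
            "targets": [
                {
                    "target_id": t.target_id,
                    "gene": t.gene,
                    "chrom": t.chrom,
                    "start": t.start,
                    "end": t.end,
                    "kind": t.kind,
                    "exon_index": t.exon_index,
                    "masked": t.masked,
                }
                for t in self.targets
            ],
            "groups": [
                {
                    "group_id": g.group_id,
                    "gene": g.gene,
                    "member_target_ids": list(g.member_target_ids),
                    "level": g.level,
                    "span": list(g.span),
                    "window_size": g.window_size,
                    "first_exon": g.first_exon,
                    "last_exon": g.last_exon,
                }
                for g in self.groups
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Panel":
        doc = json.loads(text)
        targets = [Target(**d) for d in doc["targets"]]
        groups = [
            TargetGroup(
                group_id=d["group_id"],
                gene=d["gene"],
                member_target_ids=tuple(d["member_target_ids"]),
                level=d["level"],
                span=tuple(d["span"]),
                window_size=d.get("window_size"),
                first_exon=d.get("first_exon"),
                last_exon=d.get("last_exon"),
            )
            for d in doc["groups"]
        ]
        return cls(
            name=doc["name"],
            targets=targets,
            groups=groups,
            bin_size=doc.get("bin_size"),
            window_sizes=tuple(doc.get("window_sizes", DEFAULT_WINDOW_SIZES)),
        )


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def _parse_name(name: str) -> tuple[str, int | None, str, bool]:
    """Parse a BED name field 'GENE|exNN[|masked]' or 'GENE|promoter'."""
    parts = name.split("|")
    gene = parts[0]
    exon_index: int | None = None
    kind = "exon"
    masked = "masked" in parts[1:]
    for p in parts[1:]:
        if p.startswith("ex") and p[2:].isdigit():
            exon_index = int(p[2:])
        elif p in ("promoter", "intronic"):
            kind = p
    return gene, exon_index, kind, masked


def load_panel_bed(path, gene_column: int = 3, name: str | None = None) -> Panel:
    """Read a BED4+ panel definition into exon-level targets.

    The 4th column carries ``GENE|exNN[|masked]`` labels (``GENE|promoter``
    for promoter targets).  Lines beginning with ``#`` are ignored.  Targets
    are stably sorted by (chrom, start); overlapping exons within one gene
    are rejected.
    """
    targets: list[Target] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) <= gene_column:
                raise PanelError(f"{path}:{lineno}: expected >= {gene_column + 1} columns")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: malformed coordinates: {exc}") from exc
            gene, exon_index, kind, masked = _parse_name(fields[gene_column])
            tid = f"{gene}|ex{exon_index}" if exon_index is not None else f"{gene}|{kind}|{chrom}:{start}"
            try:
                targets.append(
                    Target(tid, gene, chrom, start, end, kind, exon_index, masked)
                )
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
    targets.sort(key=lambda t: (t.chrom, t.start, t.end))
    # reject overlapping exons within a gene
    per_gene: dict[str, list[Target]] = {}
    for t in targets:
        if t.kind == "exon":
            per_gene.setdefault(t.gene, []).append(t)
    for gene, exs in per_gene.items():
        for a, b in zip(exs, exs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise PanelError(
                    f"overlapping exons in {gene}: {a.target_id} / {b.target_id}"
                )
    pname = name if name is not None else str(path)
    return Panel(name=pname, targets=targets)


def write_panel_bed(panel: Panel, path) -> None:
    """Write exon/promoter-level targets back out as BED4."""
    with open(path, "w") as fh:
        fh.write(f"# panel: {panel.name}\n")
        for t in sorted(panel.targets, key=lambda t: (t.chrom, t.start)):
            if t.kind == "bin":
                continue
            label = t.gene
            if t.exon_index is not None:
                label += f"|ex{t.exon_index}"
            elif t.kind != "exon":
                label += f"|{t.kind}"
            if t.masked:
                label += "|masked"
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{label}\n")


# ---------------------------------------------------------------------------
# binning and grouping
# ---------------------------------------------------------------------------

def _split_interval(start: int, end: int, bin_size: int) -> list[tuple[int, int]]:
    """Partition [start, end) into ceil(L/bin_size) near-equal pieces."""
    length = end - start
    n = -(-length // bin_size)  # ceil
    base, rem = divmod(length, n)
    out = []
    pos = start
    for i in range(n):
        width = base + (1 if i < rem else 0)
        out.append((pos, pos + width))
        pos += width
    return out


def make_bins(panel: Panel, bin_size: int = 200) -> Panel:
    """Partition every exon into nonoverlapping bins of ~``bin_size`` bp.

    An exon of length L yields ceil(L/bin_size) bins whose lengths differ by
    at most one base; exons at or below ``bin_size`` stay a single bin.  The
    union of a exon's bins tiles the exon exactly.  Promoter/intronic
    targets are kept but not binned (they are excluded from default
    grouping).
    """
    if bin_size < 50:
        raise PanelError(f"bin_size must be >= 50 (got {bin_size})")
    targets = [t for t in panel.targets if t.kind != "bin"]
    bins: list[Target] = []
    for t in targets:
        if t.kind != "exon":
            continue
        pieces = _split_interval(t.start, t.end, bin_size)
        for i, (s, e) in enumerate(pieces, start=1):
            bins.append(
                Target(
                    target_id=f"{t.target_id}|b{i}",
                    gene=t.gene,
                    chrom=t.chrom,
                    start=s,
                    end=e,
                    kind="bin",
                    exon_index=t.exon_index,
                    masked=t.masked,
                )
            )
    return Panel(
        name=panel.name,
        targets=targets + bins,
        groups=[],
        bin_size=bin_size,
        window_sizes=panel.window_sizes,
    )


def _exon_runs(exon_indices: list[int]) -> list[list[int]]:
    """Maximal runs of consecutive exon numbers (no bridging masked gaps)."""
    runs: list[list[int]] = []
    for e in exon_indices:
        if runs and e == runs[-1][-1] + 1:
            runs[-1].append(e)
        else:
            runs.append([e])
    return runs


def make_target_groups(
    panel: Panel,
    window_sizes: Sequence[int] | None = None,
    include_whole_gene: bool = True,
) -> Panel:
    """Build the group hierarchy: single bins, exons, exon windows, whole gene.

    Groups are built per gene over unmasked bins only.  Sliding exon windows
    (step one exon) never bridge a masked exon; the whole-gene group covers
    all unmasked bins of the gene even when masking leaves a gap.
    """
    if window_sizes is None:
        window_sizes = panel.window_sizes
    window_sizes = tuple(int(w) for w in window_sizes)
    groups: list[TargetGroup] = []
    gene_order = panel.genes
    for gene in gene_order:
        gbins = [b for b in panel.bins(gene) if not b.masked]
        if not gbins:
            continue
        chrom = gbins[0].chrom

        def span_of(members: list[Target]) -> tuple[str, int, int]:
            return (chrom, min(b.start for b in members), max(b.end for b in members))

        # single bins
        for b in gbins:
            groups.append(
                TargetGroup(
                    group_id=f"{b.target_id}|G",
                    gene=gene,
                    member_target_ids=(b.target_id,),
                    level="single_bin",
                    span=(b.chrom, b.start, b.end),
                    first_exon=b.exon_index,
                    last_exon=b.exon_index,
                )
            )
        # exon-level
        by_exon: dict[int, list[Target]] = {}
        for b in gbins:
            if b.exon_index is not None:
                by_exon.setdefault(b.exon_index, []).append(b)
        exon_ids = sorted(by_exon)
        for e in exon_ids:
            members = by_exon[e]
            groups.append(
                TargetGroup(
                    group_id=f"{gene}|ex{e}|G",
                    gene=gene,
                    member_target_ids=tuple(b.target_id for b in members),
                    level="exon",
                    span=span_of(members),
                    first_exon=e,
                    last_exon=e,
                )
            )
        # sliding multi-exon windows within runs of consecutive unmasked exons
        for w in window_sizes:
            for run in _exon_runs(exon_ids):
                for i in range(0, len(run) - w + 1):
                    sub = run[i : i + w]
                    members = [b for e in sub for b in by_exon[e]]
                    groups.append(
                        TargetGroup(
                            group_id=f"{gene}|ex{sub[0]}-{sub[-1]}|w{w}",
                            gene=gene,
                            member_target_ids=tuple(b.target_id for b in members),
                            level="multi_exon_window",
                            span=span_of(members),
                            window_size=w,
                            first_exon=sub[0],
                            last_exon=sub[-1],
                        )
                    )
        # whole gene
        if include_whole_gene:
            groups.append(
                TargetGroup(
                    group_id=f"{gene}|whole_gene",
                    gene=gene,
                    member_target_ids=tuple(b.target_id for b in gbins),
                    level="whole_gene",
                    span=span_of(gbins),
                    first_exon=min(exon_ids) if exon_ids else None,
                    last_exon=max(exon_ids) if exon_ids else None,
                )
            )
    return Panel(
        name=panel.name,
        targets=panel.targets,
        groups=groups,
        bin_size=panel.bin_size,
        window_sizes=window_sizes,
    )


def apply_mask(
    panel: Panel, mask_regions: Iterable[tuple[str, tuple[int, int]]]
) -> Panel:
    """Mask exon ranges (gene, (first, last)) and rebuild groups.

    Masked bins keep their coordinates but are excluded from grouping and
    hence from all downstream statistics.  Idempotent.
    """
    mask_regions = list(mask_regions)
    known = set(panel.genes)
    for gene, _ in mask_regions:
        if gene not in known:
            raise PanelError(f"mask references unknown gene {gene!r}")
    if not mask_regions:
        return panel

    def is_masked(t: Target) -> bool:
        if t.masked:
            return True
        if t.exon_index is None:
            return False
        for gene, (lo, hi) in mask_regions:
            if t.gene == gene and lo <= t.exon_index <= hi:
                return True
        return False

    targets = [replace(t, masked=is_masked(t)) for t in panel.targets]
    masked_panel = Panel(
        name=panel.name,
        targets=targets,
        groups=[],
        bin_size=panel.bin_size,
        window_sizes=panel.window_sizes,
    )
    if panel.groups or panel.bin_size is not None:
        return make_target_groups(masked_panel)
    return masked_panel


# ---------------------------------------------------------------------------
# demo panel (synthetic coordinates)
# ---------------------------------------------------------------------------

# Realistic per-gene exon counts and chromosome assignments for the 34-gene
# hereditary cancer predisposition panel.  Coordinates below are SYNTHETIC:
# gene placement and exon lengths are generated deterministically and do not
# correspond to any genome build.
_DEMO_GENES: tuple[tuple[str, str, int], ...] = (
    ("MUTYH", "chr1", 16),
    ("SDHB", "chr1", 8),
    ("SDHC", "chr1", 6),
    ("MSH2", "chr2", 16),
    ("MSH6", "chr2", 10),
    ("EPCAM", "chr2", 9),
    ("BARD1", "chr2", 11),
    ("MLH1", "chr3", 19),
    ("VHL", "chr3", 3),
    ("APC", "chr5", 16),
    ("PMS2", "chr7", 15),
    ("NBN", "chr8", 16),
    ("CDKN2A", "chr9", 4),
    ("PTEN", "chr10", 9),
    ("BMPR1A", "chr10", 13),
    ("RET", "chr10", 20),
    ("MEN1", "chr11", 10),
    ("ATM", "chr11", 63),
    ("SDHD", "chr11", 4),
    ("CDK4", "chr12", 8),
    ("POLE", "chr12", 49),
    ("BRCA2", "chr13", 27),
    ("PALB2", "chr16", 13),
    ("CDH1", "chr16", 16),
    ("TP53", "chr17", 11),
    ("BRCA1", "chr17", 24),
    ("BRIP1", "chr17", 20),
    ("RAD51C", "chr17", 9),
    ("RAD51D", "chr17", 10),
    ("NF1", "chr17", 58),
    ("SMAD4", "chr18", 12),
    ("STK11", "chr19", 10),
    ("POLD1", "chr19", 27),
    ("CHEK2", "chr22", 15),
)

#: Genes whose promoters are also captured by the design.
_DEMO_PROMOTER_GENES = ("APC", "MLH1", "MSH2", "PTEN")

# large internal exons (mimicking e.g. the big central exons of BRCA1/2)
_DEMO_LARGE_EXONS = {("BRCA1", 11): 3426, ("BRCA2", 11): 4932, ("APC", 16): 6574}

_DEMO_SEED = 771221


def demo_panel(
    bin_size: int = 200,
    window_sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
    masked: bool = True,
) -> Panel:
    """Build the 34-gene demo panel (synthetic coordinates), binned + grouped.

    Exon counts per gene are realistic; coordinates and exon lengths are
    synthetic and deterministic.  With ``masked=True`` the pseudogene-
    confounded PMS2/CHEK2 exons 11-15 are excluded from analysis.
    """
    import numpy as np

    rng = np.random.default_rng(_DEMO_SEED)
    targets: list[Target] = []
    cursor: dict[str, int] = {}
    for gene, chrom, n_exons in _DEMO_GENES:
        pos = cursor.get(chrom, 1_000_000) + int(rng.integers(20_000, 60_000))
        if gene in _DEMO_PROMOTER_GENES:
            plen = int(rng.integers(300, 600))
            targets.append(
                Target(f"{gene}|promoter|{chrom}:{pos}", gene, chrom, pos, pos + plen,
                       kind="promoter")
            )
            pos += plen + int(rng.integers(500, 1_500))
        for e in range(1, n_exons + 1):
            if (gene, e) in _DEMO_LARGE_EXONS:
                length = _DEMO_LARGE_EXONS[(gene, e)]
            else:
                length = int(rng.integers(90, 360))
            targets.append(
                Target(f"{gene}|ex{e}", gene, chrom, pos, pos + length, kind="exon",
                       exon_index=e)
            )
            pos += length + int(rng.integers(400, 3_000))
        cursor[chrom] = pos
    panel = Panel(name="demo-34gene-synthetic", targets=targets)
    panel = make_bins(panel, bin_size=bin_size)
    if masked:
        panel = apply_mask(
            make_target_groups(panel, window_sizes=window_sizes), DEFAULT_MASK
        )
    else:
        panel = make_target_groups(panel, window_sizes=window_sizes)
    return panel


def demo_panel_bed_path():
    """Path to the shipped synthetic 34-gene demo BED."""
    return resources.files("panelcnv") / "data" / "demo_panel_34gene_synthetic.bed"
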