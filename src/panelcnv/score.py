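"""Z / Z.adj scoring, group flagging, and merging of flags into CNV calls.

Z = (X - mu) / sigma, with mu the per-group median X across QC-passing
specimens of the batch and sigma a per-group robust dispersion (scaled
MAD) learned from a training cohort.  Z.adj divides a specimen's Z by the
standard deviation of its Z over the *other* groups of the same stratum,
cancelling specimen-level noisiness so that genuinely copy-shifted groups
stand out even in noisy specimens.  A group is flagged when |Z| or
|Z.adj| exceeds its stratum's cutoff (two-sided; the sign gives DEL vs
DUP).  Flags are projected onto bins and maximal contiguous runs of
flagged bins become CNV calls, pending orthogonal (aCGH) confirmation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .normalize import NormalizedMatrix
from .panel import Panel

__all__ = [
    "Cutoffs",
    "ScoreMatrix",
    "CnvCall",
    "batch_mu",
    "z_score",
    "z_adj",
    "flag_groups",
    "merge_calls",
    "score_matrix",
    "set_confirmation",
    "calls_to_frame",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_calls_vcf",
]

FLAG_NONE, FLAG_Z, FLAG_ZADJ, FLAG_BOTH = 0, 1, 2, 3
_SOURCE_NAMES = {FLAG_NONE: "none", FLAG_Z: "Z", FLAG_ZADJ: "Zadj", FLAG_BOTH: "both"}


@dataclass(frozen=True)
class Cutoffs:
    """Per-stratum flagging cutoffs for |Z| and |Z.adj|."""

    z: dict[str, float]
    zadj: dict[str, float]

    def __post_init__(self) -> None:
        for d in (self.z, self.zadj):
            for k, v in d.items():
                if v <= 0:
                    raise ValueError(f"cutoff for {k!r} must be positive (got {v})")


@dataclass
class ScoreMatrix:
    """Scores and flags for one scored cohort (groups x specimens)."""

    specimen_ids: list[str]
    group_ids: list[str]
    Z: pd.DataFrame
    Zadj: pd.DataFrame
    mu: pd.DataFrame  # groups x batches
    X: pd.DataFrame
    flag: pd.DataFrame  # bool
    flag_source: pd.DataFrame  # ints, see _SOURCE_NAMES
    strata: pd.Series
    batch_labels: pd.Series = None  # type: ignore[assignment]
    unscorable_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.batch_labels is None:
            self.batch_labels = pd.Series("default", index=self.specimen_ids)


@dataclass
class CnvCall:
    """A merged CNV call: one maximal run of flagged bins in one gene."""

    specimen_id: str
    gene: str
    chrom: str
    start: int
    end: int
    first_exon: int | None
    last_exon: int | None
    bins: tuple[str, ...]
    cnv_type: str  # DEL | DUP
    best_group_id: str
    max_abs_Z: float
    mean_X_ratio: float
    flag_source: str
    status: str = "flagged_pending_confirmation"


def batch_mu(
    X: NormalizedMatrix, batch_labels: pd.Series, qc_pass: pd.Series | None = None
) -> pd.DataFrame:
    """Per-group median X across QC-passing specimens of each batch."""
    if qc_pass is None:
        qc_pass = pd.Series(True, index=X.values.columns)
    by_batch: dict[str, list[str]] = {}
    for col in X.values.columns:
        by_batch.setdefault(batch_labels.loc[col], []).append(col)
    out = {}
    for batch, cols in by_batch.items():
        ok = [c for c in cols if qc_pass.get(c, True)]
        if len(ok) < 3:
            raise ValueError(
                f"batch {batch!r} has {len(ok)} QC-passing specimens (< 3); pool batches"
            )
        out[batch] = np.median(X.values[ok].to_numpy(), axis=1)
    return pd.DataFrame(out, index=X.values.index)


def z_score(
    X: NormalizedMatrix, mu: pd.DataFrame, batch_labels: pd.Series, sigma: pd.Series
) -> pd.DataFrame:
    """Elementwise (X - mu)/sigma; groups with sigma <= 0 score NaN."""
    sig = sigma.reindex(X.values.index).to_numpy()
    bad = ~(sig > 0)
    sig = np.where(bad, np.nan, sig)
    mu_per_spec = mu[batch_labels.loc[X.values.columns].to_numpy()].to_numpy()
    z = (X.values.to_numpy() - mu_per_spec) / sig[:, None]
    return pd.DataFrame(z, index=X.values.index, columns=X.values.columns)


def z_adj(Z: pd.DataFrame, strata: pd.Series) -> pd.DataFrame:
    """Z divided by the leave-one-out sample sd of same-stratum Z values.

    The denominator for group g of specimen s is the n-1 standard
    deviation of Z(s, h) over groups h != g in g's stratum.  Strata with
    fewer than 3 scorable groups, or a zero denominator, yield NaN (never
    flagged via Z.adj).
    """
    out = np.full(Z.shape, np.nan)
    zv = Z.to_numpy()
    strata = strata.reindex(Z.index)
    for stratum in strata.unique():
        rows = np.flatnonzero((strata == stratum).to_numpy())
        a = zv[rows]  # m x S
        valid = ~np.isnan(a)
        n = valid.sum(axis=0)  # per specimen
        s1 = np.nansum(a, axis=0)
        s2 = np.nansum(a * a, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n_loo = np.where(valid, n - 1, np.nan)
            sum_loo = s1 - np.where(valid, a, 0.0)
            ss_loo = s2 - np.where(valid, a * a, 0.0)
            var = (ss_loo - sum_loo**2 / n_loo) / (n_loo - 1)
            var = np.where(n_loo >= 2, var, np.nan)
            sd = np.sqrt(np.clip(var, 0.0, None))
            sd = np.where(sd > 0, sd, np.nan)
            out[rows] = a / sd
    return pd.DataFrame(out, index=Z.index, columns=Z.columns)


def flag_groups(
    Z: pd.DataFrame,
    Zadj: pd.DataFrame,
    cutoffs: Cutoffs,
    strata: pd.Series,
    rule: str = "either",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided flagging: |Z| > z_cut and/or |Zadj| > zadj_cut.

    ``rule='either'`` (the default) flags on either statistic; ``'both'``
    requires both.  NaN never flags.  Returns (flag, flag_source).
    """
    if rule not in ("either", "both"):
        raise ValueError(f"unknown rule {rule!r}")
    strata = strata.reindex(Z.index)
    zc = strata.map(cutoffs.z).to_numpy(dtype=float)[:, None]
    ac = strata.map(cutoffs.zadj).to_numpy(dtype=float)[:, None]
    with np.errstate(invalid="ignore"):
        hit_z = np.abs(Z.to_numpy()) > zc
        hit_a = np.abs(Zadj.to_numpy()) > ac
    source = np.where(hit_z, FLAG_Z, FLAG_NONE) + np.where(hit_a, FLAG_ZADJ, FLAG_NONE)
    flag = (hit_z | hit_a) if rule == "either" else (hit_z & hit_a)
    flag_df = pd.DataFrame(flag, index=Z.index, columns=Z.columns)
    src_df = pd.DataFrame(np.where(flag, source, FLAG_NONE), index=Z.index, columns=Z.columns)
    return flag_df, src_df


def score_matrix(
    X: NormalizedMatrix,
    batch_labels: pd.Series,
    sigma: pd.Series,
    cutoffs: Cutoffs,
    qc_pass: pd.Series | None = None,
    rule: str = "either",
) -> ScoreMatrix:
    """mu -> Z -> Z.adj -> flags for one cohort of normalized values."""
    mu = batch_mu(X, batch_labels, qc_pass)
    Z = z_score(X, mu, batch_labels, sigma)
    Zadj = z_adj(Z, X.strata)
    flag, source = flag_groups(Z, Zadj, cutoffs, X.strata, rule=rule)
    sig = sigma.reindex(X.values.index)
    unscorable = tuple(sig.index[~(sig > 0)])
    return ScoreMatrix(
        specimen_ids=list(X.values.columns),
        group_ids=list(X.values.index),
        Z=Z,
        Zadj=Zadj,
        mu=mu,
        X=X.values,
        flag=flag,
        flag_source=source,
        strata=X.strata,
        batch_labels=batch_labels.loc[X.values.columns].copy(),
        unscorable_groups=unscorable,
    )


def merge_calls(scores: ScoreMatrix, panel: Panel) -> list[CnvCall]:
    """Project flagged groups onto bins; contiguous flagged runs become calls.

    Per specimen per gene the flagged groups' member bins are unioned and
    maximal runs of bins adjacent in the gene's unmasked bin order form
    one call each.  The copy-ratio proxy of a run is the mean of X/mu
    over its bins (X keeps each target's capture-efficiency footprint;
    the batch median mu is the diploid reference), so DEL iff < 1; the
    best group is the flagged group of maximal |Z| overlapping the run.
    """
    group_by_id = panel.group_by_id
    calls: list[CnvCall] = []
    flag_np = scores.flag.to_numpy()
    any_flag = flag_np.any(axis=0)
    batch_of = scores.batch_labels
    # per-gene ordered unmasked bins and their single-bin group ids
    gene_bins: dict[str, list] = {
        gene: panel.bins(gene, include_masked=False) for gene in panel.genes
    }
    for si, specimen in enumerate(scores.specimen_ids):
        if not any_flag[si]:
            continue
        flagged_ids = scores.flag.index[flag_np[:, si]]
        by_gene: dict[str, set[str]] = {}
        groups_by_gene: dict[str, list[str]] = {}
        for gid in flagged_ids:
            g = group_by_id[gid]
            by_gene.setdefault(g.gene, set()).update(g.member_target_ids)
            groups_by_gene.setdefault(g.gene, []).append(gid)
        for gene, bin_set in by_gene.items():
            ordered = gene_bins[gene]
            idx = [i for i, b in enumerate(ordered) if b.target_id in bin_set]
            runs: list[list[int]] = []
            for i in idx:
                if runs and i == runs[-1][-1] + 1:
                    runs[-1].append(i)
                else:
                    runs.append([i])
            for run in runs:
                run_bins = [ordered[i] for i in run]
                run_ids = {b.target_id for b in run_bins}
                sb_groups = [f"{b.target_id}|G" for b in run_bins]
                x_run = scores.X.loc[sb_groups].iloc[:, si].to_numpy()
                mu_run = scores.mu.loc[sb_groups, batch_of.loc[specimen]].to_numpy()
                with np.errstate(invalid="ignore", divide="ignore"):
                    ratios = np.where(mu_run > 0, x_run / mu_run, np.nan)
                mean_x = float(np.nanmean(ratios))
                cnv_type = "DEL" if mean_x < 1 else "DUP"
                # best flagged group overlapping the run
                best_gid, best_z = None, -np.inf
                src = FLAG_NONE
                for gid in groups_by_gene[gene]:
                    g = group_by_id[gid]
                    if not run_ids.intersection(g.member_target_ids):
                        continue
                    zval = scores.Z.at[gid, specimen]
                    if np.isfinite(zval) and abs(zval) > best_z:
                        best_z, best_gid = abs(zval), gid
                    src |= int(scores.flag_source.at[gid, specimen])
                if best_gid is None:
                    continue
                exons = [b.exon_index for b in run_bins if b.exon_index is not None]
                calls.append(
                    CnvCall(
                        specimen_id=specimen,
                        gene=gene,
                        chrom=run_bins[0].chrom,
                        start=min(b.start for b in run_bins),
                        end=max(b.end for b in run_bins),
                        first_exon=min(exons) if exons else None,
                        last_exon=max(exons) if exons else None,
                        bins=tuple(b.target_id for b in run_bins),
                        cnv_type=cnv_type,
                        best_group_id=best_gid,
                        max_abs_Z=float(best_z),
                        mean_X_ratio=mean_x,
                        flag_source=_SOURCE_NAMES[src],
                    )
                )
    return calls


def set_confirmation(calls: list[CnvCall], confirmations: dict[tuple[str, str], str]) -> list[CnvCall]:
    """Annotate calls with orthogonal confirmation status.

    ``confirmations`` maps (specimen_id, gene) to 'confirmed' or 'refuted';
    unlisted calls stay pending.
    """
    out = []
    for c in calls:
        status = confirmations.get((c.specimen_id, c.gene))
        if status is not None:
            if status not in ("confirmed", "refuted"):
                raise ValueError(f"invalid confirmation status {status!r}")
            c = replace(c, status=status)
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# call I/O
# ---------------------------------------------------------------------------

_CALL_COLUMNS = [
    "specimen_id", "gene", "chrom", "start", "end", "first_exon", "last_exon",
    "cnv_type", "best_group_id", "max_abs_Z", "mean_X_ratio", "flag_source",
    "status", "bins",
]


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    rows = [
        {
            "specimen_id": c.specimen_id,
            "gene": c.gene,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "first_exon": c.first_exon,
            "last_exon": c.last_exon,
            "cnv_type": c.cnv_type,
            "best_group_id": c.best_group_id,
            "max_abs_Z": c.max_abs_Z,
            "mean_X_ratio": c.mean_X_ratio,
            "flag_source": c.flag_source,
            "status": c.status,
            "bins": ",".join(c.bins),
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)


def write_calls_tsv(calls: list[CnvCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[CnvCall]:
    df = pd.read_csv(path, sep="\t", dtype={"bins": str})
    out = []
    for _, r in df.iterrows():
        out.append(
            CnvCall(
                specimen_id=str(r["specimen_id"]),
                gene=str(r["gene"]),
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                first_exon=None if pd.isna(r["first_exon"]) else int(r["first_exon"]),
                last_exon=None if pd.isna(r["last_exon"]) else int(r["last_exon"]),
                bins=tuple(str(r["bins"]).split(",")) if pd.notna(r["bins"]) and str(r["bins"]) else (),
                cnv_type=str(r["cnv_type"]),
                best_group_id=str(r["best_group_id"]),
                max_abs_Z=float(r["max_abs_Z"]),
                mean_X_ratio=float(r["mean_X_ratio"]),
                flag_source=str(r["flag_source"]),
                status=str(r["status"]),
            )
        )
    return out


def write_calls_vcf(calls: list[CnvCall], path, reference: str = "synthetic") -> None:
    """Minimal VCF 4.2 with symbolic <DEL>/<DUP> ALT records."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference}\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End of variant">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=ZMAX,Number=1,Type=Float,Description="Max |Z| of flagged groups">\n')
        fh.write('##INFO=<ID=XRATIO,Number=1,Type=Float,Description="Mean normalized depth ratio">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in sorted(enumerate(calls), key=lambda ic: (ic[1].chrom, ic[1].start)):
            info = (
                f"SVTYPE={c.cnv_type};END={c.end};GENE={c.gene};"
                f"ZMAX={c.max_abs_Z:.3f};XRATIO={c.mean_X_ratio:.3f}"
            )
            fh.write(
                f"{c.chrom}\t{c.start + 1}\t{c.specimen_id}_call{i + 1}\tN\t<{c.cnv_type}>\t.\t.\t{info}\n"
            )
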