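"""Mutation catalogs: from mutation tables to channel x sample count matrices.

The central container is :class:`MutationCatalog`, the channels x samples
non-negative integer matrix that NMF factorizes. This module builds 96-
and 192-channel catalogs from MAF-like mutation tables (extracting
trinucleotide contexts from a reference when the table does not carry
them), computes territory trinucleotide-context frequencies for
cross-genome signature renormalization, and classifies mutations of a
matched tumor pair as shared or private under a detection-power filter.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .channels import (
    BASES,
    CHANNELS_96,
    CHANNELS_192,
    CONTEXTS_32,
    InvalidBaseError,
    collapse_to_pyrimidine,
    context_index,
    stranded_label,
)

logger = logging.getLogger(__name__)

_SITE_KEY = ["chrom", "pos", "ref", "alt"]


@dataclasses.dataclass
class MutationCatalog:
    """Channels x samples count matrix with fixed channel ordering."""

    channels: tuple[str, ...]
    samples: list[str]
    counts: np.ndarray  # (n_channels, n_samples), non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.channels), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.channels)} channels x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.channels), columns=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("channel").to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MutationCatalog":
        labels = tuple(frame.index)
        if labels == CHANNELS_96 or labels == CHANNELS_192:
            channels = labels
        else:
            raise ValueError("catalog rows must be the 96 or 192 channel labels in order")
        return cls(channels, [str(c) for c in frame.columns], frame.to_numpy())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))

    def collapse_strands(self) -> "MutationCatalog":
        """Marginalize a 192-channel catalog over strand to 96 channels."""
        if self.channels != CHANNELS_192:
            raise ValueError("collapse_strands requires a 192-channel catalog")
        folded = self.counts.reshape(96, 2, -1).sum(axis=1)
        return MutationCatalog(CHANNELS_96, list(self.samples), folded)


@dataclasses.dataclass
class ContextFrequencyTable:
    """Relative frequencies of the 32 pyrimidine-centered trinucleotides."""

    frequency: np.ndarray  # (32,), sums to 1
    territory_name: str = ""
    contexts: tuple[str, ...] = CONTEXTS_32

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        if self.frequency.shape != (len(self.contexts),):
            raise ValueError("frequency vector must have one entry per context")
        if (self.frequency < 0).any():
            raise ValueError("context frequencies must be non-negative")
        if abs(self.frequency.sum() - 1.0) > 1e-9:
            raise ValueError("context frequencies must sum to 1")

    def to_series(self) -> pd.Series:
        return pd.Series(self.frequency, index=list(self.contexts), name=self.territory_name)

    def to_tsv(self, path: str | Path) -> None:
        self.to_series().rename_axis("context").to_csv(path, sep="\t", header=True)

    @classmethod
    def from_tsv(cls, path: str | Path, territory_name: str = "") -> "ContextFrequencyTable":
        s = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]
        s = s.reindex(list(CONTEXTS_32))
        if s.isna().any():
            raise ValueError("frequency table must cover all 32 pyrimidine contexts")
        return cls(s.to_numpy(), territory_name or str(s.name))


@dataclasses.dataclass
class PowerModel:
    """Binomial detection-power model.

    A mutation is considered detectable when at least ``min_alt_reads``
    alternate reads are expected under Binomial(depth, expected VAF);
    ``error_rate`` is the per-base sequencing error folded into the
    effective alternate-read probability.
    """

    min_alt_reads: int = 3
    error_rate: float = 0.0
    power_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.power_threshold < 1:
            raise ValueError("power_threshold must lie strictly between 0 and 1")
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")


@dataclasses.dataclass
class CatalogQC:
    """Per-build exclusion counters for catalog construction."""

    n_input: int = 0
    n_retained: int = 0
    n_indel: int = 0
    n_ambiguous_context: int = 0
    n_ref_mismatch: int = 0
    n_unassigned_strand: int = 0

    def as_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like tab-separated mutation table.

    Required columns: sample, chrom, pos (1-based), ref, alt. Optional
    columns (ccf, subclone, strand, t_depth, t_alt_count, context5,
    context3, mate_depth, mate_vaf, ...) pass through untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in ("sample", "chrom", "pos", "ref", "alt") if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table {path} is missing columns: {missing}")
    df["pos"] = df["pos"].astype(np.int64)
    return df


def read_vcf_positions(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read positions and alleles (only) from a VCF into the table schema."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alts = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            for alt in alts.split(","):
                rows.append((sample_id, chrom, pos, ref, alt))
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt"])


def read_bed3(path: str | Path) -> pd.DataFrame:
    """Read BED3 intervals (0-based half-open)."""
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={0: str}, comment="#",
    )
    if (bed["end"] <= bed["start"]).any():
        raise ValueError("BED intervals must have end > start")
    return bed


def _context_from_reference(reference, chrom: str, pos: int) -> tuple[str, str, str]:
    """(flank5, ref_base, flank3) at a 1-based position, uppercase."""
    seq = str(reference[chrom][pos - 2 : pos + 1]).upper()
    if len(seq) != 3:
        raise IndexError(f"position {chrom}:{pos} too close to the contig edge")
    return seq[0], seq[1], seq[2]


def assign_channels(
    df: pd.DataFrame, reference=None, qc: CatalogQC | None = None
) -> pd.DataFrame:
    """Annotate rows with channel96 index/label; drop non-SNVs and bad contexts."""
    qc = qc if qc is not None else CatalogQC()
    qc.n_input += len(df)
    keep_idx: list[int] = []
    chan_idx: list[int] = []
    chan_lab: list[str] = []
    for row in df.itertuples():
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or "-" in (ref, alt):
            qc.n_indel += 1
            continue
        f5 = getattr(row, "context5", None)
        f3 = getattr(row, "context3", None)
        if (f5 is None or f3 is None or pd.isna(f5) or pd.isna(f3)) and reference is not None:
            try:
                f5, ref_base, f3 = _context_from_reference(reference, str(row.chrom), int(row.pos))
            except (KeyError, IndexError):
                qc.n_ambiguous_context += 1
                continue
            if ref_base != ref:
                qc.n_ref_mismatch += 1
                logger.warning(
                    "ref mismatch at %s:%d: table says %s, reference says %s — excluded",
                    row.chrom, row.pos, ref, ref_base,
                )
                continue
        if f5 is None or f3 is None or pd.isna(f5) or pd.isna(f3):
            raise ValueError(
                "mutation table lacks context5/context3 columns and no reference was given"
            )
        f5, f3 = str(f5).upper(), str(f3).upper()
        try:
            idx, lab = collapse_to_pyrimidine(ref, alt, f5, f3)
        except InvalidBaseError:
            qc.n_ambiguous_context += 1
            continue
        keep_idx.append(row.Index)
        chan_idx.append(idx)
        chan_lab.append(lab)
    out = df.loc[keep_idx].copy()
    out["channel96"] = chan_idx
    out["channel"] = chan_lab
    qc.n_retained += len(out)
    return out


def build_catalog(
    mutations: pd.DataFrame,
    reference=None,
    samples: Sequence[str] | None = None,
) -> tuple[MutationCatalog, CatalogQC]:
    """Build a 96-channel catalog from a mutation table.

    Contexts are taken from ``context5``/``context3`` columns when
    present, otherwise extracted from ``reference`` (an indexed FASTA,
    e.g. a ``pyfaidx.Fasta``). Indels, records with ambiguous context
    bases and records whose stated ref allele contradicts the reference
    are excluded and counted in the QC report. Column sums equal the
    number of retained SNVs per sample.
    """
    qc = CatalogQC()
    annotated = assign_channels(mutations, reference, qc)
    sample_list = list(samples) if samples is not None else sorted(annotated["sample"].unique())
    counts = np.zeros((96, len(sample_list)), dtype=np.int64)
    col = {s: j for j, s in enumerate(sample_list)}
    for row in annotated.itertuples():
        j = col.get(row.sample)
        if j is not None:
            counts[row.channel96, j] += 1
    return MutationCatalog(CHANNELS_96, sample_list, counts), qc


_STRAND_ALIASES = {
    "coding": "+", "+": "+", "untranscribed": "+",
    "noncoding": "-", "-": "-", "transcribed": "-",
}


def build_stranded_catalog(
    mutations: pd.DataFrame,
    reference=None,
    samples: Sequence[str] | None = None,
) -> tuple[MutationCatalog, CatalogQC]:
    """Build a 192-channel catalog from records with a strand class.

    The ``strand`` column gives the transcriptional strand of each
    mutation's pyrimidine representation: ``coding``/``+`` for the
    untranscribed strand of the gene, ``noncoding``/``-`` for the
    transcribed strand. Records without an assignment are excluded and
    counted; marginalizing the result over strand reproduces
    :func:`build_catalog` on the retained records.
    """
    if "strand" not in mutations.columns:
        raise ValueError("stranded catalog requires a 'strand' column")
    qc = CatalogQC()
    strand = mutations["strand"].map(lambda s: _STRAND_ALIASES.get(str(s).lower()))
    assigned = mutations.loc[strand.notna()].copy()
    assigned["strand_pm"] = strand[strand.notna()]
    qc.n_unassigned_strand = len(mutations) - len(assigned)
    if assigned.empty:
        raise ValueError("no records carry a usable strand assignment")
    annotated = assign_channels(assigned, reference, qc)
    sample_list = list(samples) if samples is not None else sorted(annotated["sample"].unique())
    counts = np.zeros((192, len(sample_list)), dtype=np.int64)
    col = {s: j for j, s in enumerate(sample_list)}
    chan192 = {lab: i for i, lab in enumerate(CHANNELS_192)}
    for row in annotated.itertuples():
        j = col.get(row.sample)
        if j is not None:
            counts[chan192[stranded_label(row.channel, row.strand_pm)], j] += 1
    return MutationCatalog(CHANNELS_192, sample_list, counts), qc


def compute_context_frequencies(
    reference,
    intervals: pd.DataFrame | None = None,
    territory_name: str = "",
) -> ContextFrequencyTable:
    """Trinucleotide-context frequencies of a genomic territory.

    Every interval position contributes one window centered on it; the
    flanking bases are read from the reference even when they fall
    outside the interval (exome capture sequences the flanking context).
    Purine-centered windows are recorded under their reverse-complement
    (pyrimidine-centered) spelling. Windows containing ambiguous bases
    or overhanging a contig edge are skipped.

    ``intervals`` is a BED3-style frame (chrom, start, end; 0-based
    half-open); ``None`` means every position of every contig.
    """
    counts = np.zeros(32, dtype=np.int64)
    base_code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        base_code[ord(b)] = i
        base_code[ord(b.lower())] = i
    # context index lookup for all 64 trinucleotides, pyrimidine-collapsed
    tri_index = np.full(64, -1, dtype=np.int8)
    for i5 in range(4):
        for ic in range(4):
            for i3 in range(4):
                tri = BASES[i5] + BASES[ic] + BASES[i3]
                tri_index[i5 * 16 + ic * 4 + i3] = context_index(tri)

    def _count_window(seq_codes: np.ndarray) -> None:
        if len(seq_codes) < 3:
            return
        c5, cc, c3 = seq_codes[:-2], seq_codes[1:-1], seq_codes[2:]
        valid = (c5 >= 0) & (cc >= 0) & (c3 >= 0)
        codes = (c5[valid].astype(np.int32) * 16 + cc[valid] * 4 + c3[valid])
        np.add.at(counts, tri_index[codes], 1)

    if intervals is None:
        names = reference.keys() if hasattr(reference, "keys") else list(reference)
        for chrom in names:
            seq = str(reference[chrom][:]).upper()
            _count_window(base_code[np.frombuffer(seq.encode(), dtype=np.uint8)])
    else:
        for row in intervals.itertuples():
            chrom_len = len(reference[row.chrom])
            # fetch one flank base either side; windows of the slice are
            # exactly the interval centers whose flanks exist on the contig
            lo = max(int(row.start) - 1, 0)
            hi = min(int(row.end) + 1, chrom_len)
            seq = str(reference[row.chrom][lo:hi]).upper()
            _count_window(base_code[np.frombuffer(seq.encode(), dtype=np.uint8)])
    total = counts.sum()
    if total == 0:
        raise ValueError("territory contains no countable trinucleotide windows")
    return ContextFrequencyTable(counts / total, territory_name)


def detection_power(
    depth: int | np.ndarray,
    expected_vaf: float | np.ndarray,
    model: PowerModel | None = None,
) -> float | np.ndarray:
    """Probability of observing >= min_alt_reads alternate reads.

    Computed as the upper binomial tail P(X >= m) with
    X ~ Binomial(depth, p) where p folds the sequencing error rate into
    the expected variant allele fraction. Monotone non-decreasing in
    depth and in expected_vaf.
    """
    model = model or PowerModel()
    depth = np.asarray(depth)
    vaf = np.asarray(expected_vaf, dtype=float)
    if (vaf < 0).any() or (vaf > 1).any():
        raise ValueError("expected_vaf must lie in [0, 1]")
    e = model.error_rate
    p = vaf * (1 - e) + (1 - vaf) * e / 3  # misread of a ref base hits the alt 1/3 of the time
    power = stats.binom.sf(model.min_alt_reads - 1, depth, p)
    return float(power) if power.ndim == 0 else power


def classify_shared_private(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    model: PowerModel | None = None,
) -> pd.DataFrame:
    """Timing classification of one patient's paired mutation tables.

    A site detected in both tumors is ``shared``. A site detected in
    only one tumor is ``pre_only``/``post_only`` when the mate tumor had
    power >= the model threshold to detect it (columns ``mate_depth``
    and ``mate_vaf`` give the mate tumor's depth and expected VAF at the
    site), and ``unpowered`` otherwise — unpowered sites are excluded
    from pre/post load comparisons. Returns the concatenated tables with
    a ``timing`` column (shared sites appear once per input table).
    """
    model = model or PowerModel()
    if pre.empty and post.empty:
        return pd.concat([pre, post]).assign(timing=pd.Series(dtype=str))
    for name, df in (("pre", pre), ("post", post)):
        if not df.empty and df["sample"].nunique() > 1:
            raise ValueError(f"{name} table mixes samples; classify one pair at a time")
    pre_keys = set(map(tuple, pre[_SITE_KEY].itertuples(index=False))) if not pre.empty else set()
    post_keys = set(map(tuple, post[_SITE_KEY].itertuples(index=False))) if not post.empty else set()
    shared = pre_keys & post_keys

    def _label(df: pd.DataFrame, own: str) -> pd.Series:
        labels = []
        for row in df.itertuples():
            key = (row.chrom, row.pos, row.ref, row.alt)
            if key in shared:
                labels.append("shared")
                continue
            mate_depth = getattr(row, "mate_depth", None)
            mate_vaf = getattr(row, "mate_vaf", None)
            if mate_depth is None or mate_vaf is None or pd.isna(mate_depth) or pd.isna(mate_vaf):
                labels.append("unpowered")
                continue
            power = detection_power(int(mate_depth), float(mate_vaf), model)
            labels.append(own if power >= model.power_threshold else "unpowered")
        return pd.Series(labels, index=df.index, dtype=str)

    out = []
    if not pre.empty:
        out.append(pre.assign(timing=_label(pre, "pre_only")))
    if not post.empty:
        out.append(post.assign(timing=_label(post, "post_only")))
    return pd.concat(out, ignore_index=True)


def classify_cohort(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    patients: Iterable[str] | None = None,
    model: PowerModel | None = None,
    patient_col: str = "patient",
) -> pd.DataFrame:
    """Apply :func:`classify_shared_private` per patient across a cohort."""
    if patient_col not in pre.columns or patient_col not in post.columns:
        raise ValueError(f"both tables need a {patient_col!r} column for pairing")
    pre_pat, post_pat = set(pre[patient_col]), set(post[patient_col])
    if pre_pat != post_pat:
        raise ValueError(
            f"unmatched patient ids: pre-only {sorted(pre_pat - post_pat)}, "
            f"post-only {sorted(post_pat - pre_pat)}"
        )
    patients = list(patients) if patients is not None else sorted(pre_pat)
    pieces = [
        classify_shared_private(
            pre[pre[patient_col] == p], post[post[patient_col] == p], model
        )
        for p in patients
    ]
    return pd.concat(pieces, ignore_index=True)
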