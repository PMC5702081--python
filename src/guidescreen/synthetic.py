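"""Synthetic pooled-screen data with known ground truth.

Generates guide reference libraries, screen FASTQ files and count matrices
whose true per-guide read tallies are recorded, so the filtering, counting
and statistics modules can be validated end to end without external data.

The model: each gene carries a fixed number of distinct guides (default 5,
as in genome-wide knockout libraries); each guide's expected abundance is
drawn log-normally (representing uneven library representation); in the
experimental (selected) library the expected abundance of a guide is
multiplied by its gene's fold change (f >= 1 for enriched genes, 1/f for
depleted, 1 otherwise).  Per-library counts are a single multinomial draw
over the normalized expected abundances, so the library size is exact.
Reads take the form [random prefix][anchor][guide][random suffix] at a
fixed read length, with the anchor offset chosen uniformly so that the
guide always fits; a configurable fraction of junk reads contains no anchor
at all.  All outputs are fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from guidescreen.fastq_filter import DEFAULT_ANCHOR, DEFAULT_GUIDE_LENGTH
from guidescreen.guide_report import GuideCounts, GuideReference

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ScreenDesign:
    """Parameters of a synthetic pooled CRISPR screen."""

    n_genes: int = 100
    guides_per_gene: int = 5
    guide_length: int = DEFAULT_GUIDE_LENGTH
    anchor: str = DEFAULT_ANCHOR
    read_length: int = 75
    baseline_sigma: float = 1.0          # log-normal sd of expected guide abundance
    enriched_genes: tuple[str, ...] = ()
    depleted_genes: tuple[str, ...] = ()
    fold_change: float = 8.0
    reads_per_library: int = 100_000
    anchor_free_fraction: float = 0.0
    low_quality_fraction: float = 0.0    # reads given uniformly low (Q2) qualities
    seed: int = 0

    def __post_init__(self):
        self.enriched_genes = tuple(self.enriched_genes)
        self.depleted_genes = tuple(self.depleted_genes)
        if set(self.enriched_genes) & set(self.depleted_genes):
            raise ValueError("a gene cannot be both enriched and depleted")
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be >= 1 (depletion uses its reciprocal)")
        if not 0.0 <= self.anchor_free_fraction < 1.0:
            raise ValueError("anchor_free_fraction must lie in [0, 1)")
        if self.read_length < len(self.anchor) + self.guide_length:
            raise ValueError("read_length too short for anchor + guide")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"gene{str(i + 1).zfill(width)}" for i in range(self.n_genes)]


def _random_kmers(rng: np.random.Generator, n: int, k: int, max_tries: int = 50) -> list[str]:
    """n distinct random ACGT k-mers; errors out if collisions persist."""
    if 4.0**k <= 4 * n:
        raise ValueError(f"cannot draw {n} distinct {k}-mers")
    seqs: dict[str, None] = {}
    for _ in range(max_tries):
        need = n - len(seqs)
        if need == 0:
            break
        block = _BASES[rng.integers(0, 4, size=(need, k))]
        for row in block:
            seqs.setdefault(row.tobytes().decode(), None)
    if len(seqs) < n:
        raise RuntimeError(f"failed to draw {n} distinct {k}-mers after {max_tries} rounds")
    return list(seqs)[:n]


def make_reference(design: ScreenDesign, path: str | Path | None = None) -> GuideReference:
    """Deterministic guide reference with columns (gene, guide_id, sequence).

    Optionally also writes the reference as a headered CSV.
    """
    rng = np.random.default_rng([design.seed, 0])
    n_guides = design.n_genes * design.guides_per_gene
    sequences = _random_kmers(rng, n_guides, design.guide_length)
    genes = np.repeat(design.gene_names, design.guides_per_gene)
    guide_ids = [f"{gene}_g{i % design.guides_per_gene + 1}" for i, gene in enumerate(genes)]
    df = pd.DataFrame({"gene": genes, "guide_id": guide_ids, "sequence": sequences})
    if path is not None:
        df.to_csv(path, index=False)
    table = df[["gene", "guide_id"]].copy()
    table.index = pd.Index(df["sequence"], name="sequence")
    return GuideReference(table, "sequence", ("gene", "guide_id"))


def _expected_abundance(design: ScreenDesign, reference: GuideReference) -> tuple[np.ndarray, np.ndarray]:
    """(control, experimental) expected per-guide abundances (unnormalized)."""
    rng = np.random.default_rng([design.seed, 1])
    n = len(reference)
    baseline = rng.lognormal(mean=0.0, sigma=design.baseline_sigma, size=n)
    fold = np.ones(n)
    genes = reference.table["gene"].to_numpy()
    fold[np.isin(genes, design.enriched_genes)] = design.fold_change
    fold[np.isin(genes, design.depleted_genes)] = 1.0 / design.fold_change
    return baseline, baseline * fold


def draw_guide_counts(expected: np.ndarray, n_reads: int, seed) -> np.ndarray:
    """One multinomial draw of n_reads over normalized expected abundances."""
    expected = np.asarray(expected, dtype=float)
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_reads, expected / expected.sum())


def make_screen_counts(
    design: ScreenDesign, reference: GuideReference | None = None
) -> tuple[GuideCounts, GuideCounts, pd.DataFrame]:
    """Draw per-guide counts for control and experimental libraries.

    Returns (control, experimental, truth) where truth is a per-guide table
    of the drawn counts with gene labels.  This is the count stage of
    :func:`make_screen_fastq` without read synthesis; the same draws feed
    both.
    """
    if reference is None:
        reference = make_reference(design)
    baseline, treated = _expected_abundance(design, reference)
    n_junk = int(round(design.anchor_free_fraction * design.reads_per_library))
    n_guide_reads = design.reads_per_library - n_junk
    ctrl = draw_guide_counts(baseline, n_guide_reads, [design.seed, 2])
    exp = draw_guide_counts(treated, n_guide_reads, [design.seed, 3])
    guides = reference.guides
    truth = pd.DataFrame(
        {
            "gene": reference.table["gene"].to_numpy(),
            "guide_id": reference.table["guide_id"].to_numpy(),
            "sequence": guides,
            "control_count": ctrl,
            "experimental_count": exp,
        }
    )
    control = GuideCounts(dict(zip(guides, (int(c) for c in ctrl))), unmapped=0,
                          library_label="control")
    experimental = GuideCounts(dict(zip(guides, (int(c) for c in exp))), unmapped=0,
                               library_label="experimental")
    return control, experimental, truth


@dataclass
class ScreenTruth:
    """Ground truth of one generated screen."""

    reference_path: Path
    control_path: Path
    experimental_path: Path
    truth: pd.DataFrame                       # per-guide drawn counts
    anchor_free: dict[str, int] = field(default_factory=dict)  # per-library junk tallies

    def save_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, index=False)


def _synthesize_library(
    rng: np.random.Generator,
    design: ScreenDesign,
    guides: list[str],
    counts: np.ndarray,
    n_junk: int,
    label: str,
    path: Path,
) -> None:
    """Write one library's FASTQ: guide reads in random order among junk reads.

    Guide reads place the anchor at a uniform random offset; prefixes are
    re-drawn in the rare case a random flank creates an earlier anchor
    occurrence, so that anchor search-and-trim recovers the intended guide
    for every read.  Junk reads are guaranteed anchor-free.
    """
    anchor = design.anchor
    glen = design.guide_length
    rlen = design.read_length
    flank = rlen - len(anchor) - glen  # random bases split between prefix and suffix
    assignment = np.concatenate([np.repeat(np.arange(len(guides)), counts),
                                 np.full(n_junk, -1, dtype=np.int64)])
    rng.shuffle(assignment)
    prefix_lens = rng.integers(0, flank + 1, size=len(assignment))
    n_random = np.where(assignment >= 0, flank, rlen)
    chars = _BASES[rng.integers(0, 4, size=int(n_random.sum()))].tobytes().decode()
    hi_qual = "I" * rlen
    lo_qual = "#" * rlen
    low_mask = (
        rng.random(len(assignment)) < design.low_quality_fraction
        if design.low_quality_fraction > 0
        else np.zeros(len(assignment), dtype=bool)
    )
    offset = 0
    with open(path, "w") as out:
        for i, gi in enumerate(assignment):
            budget = int(n_random[i])
            rand = chars[offset : offset + budget]
            offset += budget
            if gi >= 0:
                pl = int(prefix_lens[i])
                seq = rand[:pl] + anchor + guides[gi] + rand[pl:]
                while seq.find(anchor) != pl:  # flank spawned a spurious earlier anchor
                    rand = _BASES[rng.integers(0, 4, size=budget)].tobytes().decode()
                    seq = rand[:pl] + anchor + guides[gi] + rand[pl:]
            else:
                seq = rand
                while anchor in seq:
                    seq = _BASES[rng.integers(0, 4, size=rlen)].tobytes().decode()
            qual = lo_qual if low_mask[i] else hi_qual
            out.write(f"@{label}_{i}\n{seq}\n+\n{qual}\n")


def make_screen_fastq(design: ScreenDesign, out_dir: str | Path) -> ScreenTruth:
    """Generate reference CSV, control and experimental FASTQs, and truth.

    Per-guide counts come from :func:`make_screen_counts`; read synthesis
    only arranges those exact tallies into amplicon-shaped reads, so the
    truth table is exact for the generated files.  Deterministic per seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_path = out_dir / "reference.csv"
    reference = make_reference(design, ref_path)
    control, experimental, truth = make_screen_counts(design, reference)
    n_junk = int(round(design.anchor_free_fraction * design.reads_per_library))
    guides = reference.guides
    ctrl_path = out_dir / "control.fastq"
    exp_path = out_dir / "experimental.fastq"
    ctrl_counts = np.array([control.counts[g] for g in guides])
    exp_counts = np.array([experimental.counts[g] for g in guides])
    _synthesize_library(np.random.default_rng([design.seed, 4]), design, guides,
                        ctrl_counts, n_junk, "control", ctrl_path)
    _synthesize_library(np.random.default_rng([design.seed, 5]), design, guides,
                        exp_counts, n_junk, "experimental", exp_path)
    return ScreenTruth(
        reference_path=ref_path,
        control_path=ctrl_path,
        experimental_path=exp_path,
        truth=truth,
        anchor_free={"control": n_junk, "experimental": n_junk},
    )


def make_null_ratio_matrix(n_genes: int, n_guides: int, seed) -> np.ndarray:
    """Per-gene i.i.d. standard-normal log2-ratio vectors (the exact null).

    Feeds the z-test's ratio stage directly, bypassing counting, so the
    test's null distribution can be checked against closed-form theory.
    """
    if n_guides < 2:
        raise ValueError("n_guides must be >= 2")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_genes, n_guides))
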