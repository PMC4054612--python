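"""Synthetic study generator: every input the pipeline needs, with
recorded ground truth.

The generator emulates a matched tumour/normal small RNA-seq experiment:
a random ~100 kb genome carrying annotated miRNAs (20-23 nt, length mode
22), snoRNAs, tRNA-fragment sources and coding exons (including
deliberately multi-copy miRNAs to exercise fractional counting);
per-library reads drawn from a negative-binomial model
(``Var = mu + alpha * mu^2``) with log-uniform library size factors and
spiked fold changes in the cancer group; fixed-length machine reads with
a 3' adapter and a low-quality tail so clipping and trimming are always
exercised; and downstream evidence tables (interaction databases with
true and decoy support, DE gene lists, GO map with one enriched-by-
construction category, PPI edges).

All randomness flows from a single root seed through named substreams,
so every artefact is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import DEFAULT_ADAPTER
from .io import FeatureAnnotation, write_fastq

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),)))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# Designs and truth
# ---------------------------------------------------------------------------

@dataclass
class GenomeDesign:
    genome_length: int = 100_000
    chrom: str = "chr1"
    n_mirna: int = 60             # miRNA annotation records
    n_snorna: int = 10
    n_trf: int = 5                # tRNA-fragment sources
    n_exon: int = 20              # coding exons
    n_multicopy: int = 2          # miRNAs present at several identical loci
    multicopy_loci: int = 3


@dataclass
class LibraryDesign:
    """Paired design: patient i contributes control N<i> and cancer C<i>."""

    n_pairs: int = 9
    reads_per_library: int = 20_000
    machine_length: int = 36
    adapter: str = DEFAULT_ADAPTER
    degradation_rate: float = 0.05
    n_singletons: int = 10

    @property
    def libraries(self) -> list[str]:
        return [f"N{i}" for i in range(1, self.n_pairs + 1)] + [
            f"C{i}" for i in range(1, self.n_pairs + 1)
        ]

    @property
    def groups(self) -> dict[str, str]:
        return {lib: lib[0] for lib in self.libraries}

    @property
    def pairs(self) -> dict[str, str]:
        return {lib: lib[1:] for lib in self.libraries}


@dataclass
class SyntheticTruth:
    """Ground truth for downstream recovery tests."""

    feature_expression: pd.DataFrame      # features x {control, cancer} mean expression
    spiked_log2fc: dict[str, float]
    dispersion: pd.Series                 # per-feature NB dispersion alpha
    true_targets: dict[str, set[str]] = field(default_factory=dict)
    outlier_samples: set[str] = field(default_factory=set)

    @property
    def features(self) -> list[str]:
        return list(self.feature_expression.index)

    def to_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        expr = self.feature_expression.copy()
        expr["dispersion"] = self.dispersion
        expr["spiked_log2fc"] = pd.Series(self.spiked_log2fc).reindex(expr.index).fillna(0.0)
        expr.to_csv(outdir / "truth_expression.tsv", sep="\t", index_label="feature")
        meta = {
            "true_targets": {m: sorted(g) for m, g in sorted(self.true_targets.items())},
            "outlier_samples": sorted(self.outlier_samples),
        }
        with open(outdir / "truth.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def make_genome_and_annotation(
    design: GenomeDesign | None = None, seed: int = 0
) -> tuple[dict[str, str], list[FeatureAnnotation]]:
    """Random genome plus non-overlapping feature annotation.

    Multi-copy miRNAs share one feature_id and one mature sequence across
    ``multicopy_loci`` distinct loci (the sequence is written into the
    genome at each locus).  miRNA lengths are drawn from {20..23} with 22
    most likely, so simulated libraries peak at 22 nt after clipping.
    """
    design = design or GenomeDesign()
    rng = substream(seed, "genome")
    L = design.genome_length
    genome_arr = _BASES[rng.integers(0, 4, size=L)]
    occupied = np.zeros(L, dtype=bool)

    def place(length: int) -> tuple[int, int]:
        for _ in range(2000):
            start = int(rng.integers(0, L - length))
            if not occupied[max(0, start - 2) : start + length + 2].any():
                occupied[start : start + length] = True
                return start, start + length
        raise ValueError("genome too short to place all features")

    features: list[FeatureAnnotation] = []
    mirna_lengths = rng.choice([20, 21, 22, 23], p=[0.10, 0.15, 0.60, 0.15],
                               size=design.n_mirna)

    # Multi-copy miRNAs first: one id, one mature sequence, several loci.
    record = 0
    mir_index = 0
    for m in range(design.n_multicopy):
        mir_index += 1
        fid = f"mir-{mir_index}"
        length = int(mirna_lengths[record])
        mature = _random_seq(rng, length)
        for _ in range(design.multicopy_loci):
            start, end = place(length)
            strand = "+" if rng.random() < 0.5 else "-"
            piece = mature if strand == "+" else _revcomp(mature)
            genome_arr[start:end] = list(piece)
            features.append(
                FeatureAnnotation(fid, "miRNA", design.chrom, start, end, strand)
            )
            record += 1

    while record < design.n_mirna:
        mir_index += 1
        length = int(mirna_lengths[record])
        start, end = place(length)
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            FeatureAnnotation(f"mir-{mir_index}", "miRNA", design.chrom, start, end, strand)
        )
        record += 1

    for cls, prefix, n, lo, hi in (
        ("snoRNA", "sno", design.n_snorna, 70, 100),
        ("tRNA_fragment", "trf", design.n_trf, 28, 34),
        ("coding_exon", "exon", design.n_exon, 100, 200),
    ):
        for i in range(1, n + 1):
            length = int(rng.integers(lo, hi + 1))
            start, end = place(length)
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                FeatureAnnotation(f"{prefix}-{i}", cls, design.chrom, start, end, strand)
            )

    genome = {design.chrom: "".join(genome_arr)}
    return genome, features


def mature_sequence(genome: dict[str, str], feature: FeatureAnnotation) -> str:
    """Mature (read-orientation) sequence of a feature."""
    seq = genome[feature.chrom][feature.start : feature.end]
    return seq if feature.strand == "+" else _revcomp(seq)


# ---------------------------------------------------------------------------
# Expression truth
# ---------------------------------------------------------------------------

def build_truth(
    annotation: list[FeatureAnnotation],
    design: LibraryDesign | None = None,
    n_spiked: int = 20,
    spike_log2fc: float = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
    outlier_library: str | None = None,
    targets_per_mirna: tuple[int, int] = (6, 10),
) -> SyntheticTruth:
    """Draw per-feature mean expression and plant recoverable effects.

    Spiked features (miRNA/snoRNA only) get means in [100, 500] and
    alternating-sign log2 fold changes of magnitude ``spike_log2fc``;
    remaining features are scaled so the expected per-library sncRNA read
    mass matches the design depth (95% of it, leaving 5% for
    degradation).
    """
    design = design or LibraryDesign()
    rng = substream(seed, "truth")
    ncrna_ids: list[str] = []
    classes: dict[str, str] = {}
    for f in annotation:
        if f.feature_class in ("miRNA", "snoRNA", "tRNA_fragment", "other_ncRNA"):
            if f.feature_id not in classes:
                classes[f.feature_id] = f.feature_class
                ncrna_ids.append(f.feature_id)
    spikable = [i for i in ncrna_ids if classes[i] in ("miRNA", "snoRNA")]
    if n_spiked > len(spikable):
        raise ValueError(f"cannot spike {n_spiked} of {len(spikable)} eligible features")
    spiked = sorted(rng.choice(spikable, size=n_spiked, replace=False).tolist())
    signs = np.where(np.arange(n_spiked) % 2 == 0, -1.0, 1.0)
    spiked_fc = {f: float(s * spike_log2fc) for f, s in zip(spiked, signs)}

    mu = pd.Series(rng.lognormal(mean=np.log(120.0), sigma=1.0, size=len(ncrna_ids)),
                   index=ncrna_ids).clip(5.0, 2000.0)
    mu[spiked] = rng.uniform(100.0, 500.0, size=n_spiked)
    target_mass = design.reads_per_library * (1.0 - design.degradation_rate)
    other = [i for i in ncrna_ids if i not in spiked_fc]
    spiked_mass = float(mu[spiked].sum())
    if spiked_mass > target_mass:
        raise ValueError("requested spiked expression exceeds the design depth")
    if other:
        mu[other] *= (target_mass - spiked_mass) / float(mu[other].sum())

    fc = pd.Series(0.0, index=ncrna_ids)
    fc.update(pd.Series(spiked_fc))
    expr = pd.DataFrame({"control": mu, "cancer": mu * np.power(2.0, fc)})

    # Planted targets: down-miRNAs repress genes destined for the UP list
    # and vice versa.
    true_targets: dict[str, set[str]] = {}
    up_pool = [f"UT{i:03d}" for i in range(1, 41)]
    down_pool = [f"DT{i:03d}" for i in range(1, 41)]
    lo, hi = targets_per_mirna
    for f, v in sorted(spiked_fc.items()):
        if classes[f] != "miRNA":
            continue
        pool = up_pool if v < 0 else down_pool
        k = int(rng.integers(lo, hi + 1))
        true_targets[f] = set(rng.choice(pool, size=k, replace=False).tolist())

    outliers = {outlier_library} if outlier_library else set()
    return SyntheticTruth(expr, spiked_fc, pd.Series(dispersion, index=ncrna_ids),
                          true_targets, outliers)


# ---------------------------------------------------------------------------
# Count and read simulation
# ---------------------------------------------------------------------------

def draw_size_factors(design: LibraryDesign, seed: int) -> pd.Series:
    rng = substream(seed, "size_factors")
    s = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(design.libraries)))
    return pd.Series(s, index=design.libraries)


def simulate_count_matrix(
    truth: SyntheticTruth, design: LibraryDesign, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """True per-feature read counts per library (NB sampling).

    The planted outlier library's per-feature means are multiplied by a
    large random per-feature distortion (2^N(0,4)), displacing it far
    from the sample cloud in expression space.
    """
    rng = substream(seed, "counts")
    s = draw_size_factors(design, seed)
    features = truth.features
    counts = pd.DataFrame(0, index=features, columns=design.libraries, dtype=np.int64)
    alpha = truth.dispersion.reindex(features).to_numpy(dtype=float)
    for lib in design.libraries:
        group = "cancer" if lib.startswith("C") else "control"
        mean = truth.feature_expression[group].reindex(features).to_numpy(dtype=float) * s[lib]
        if lib in truth.outlier_samples:
            # library-wide multiplicative distortion, rescaled so the
            # library keeps its nominal depth while losing its profile;
            # the magnitude is chosen so the displaced library exceeds the
            # 4-SD outlier criterion by construction (a single outlier
            # among m samples can reach at most sqrt(m-1) SDs, so the
            # distortion must dominate the biological spread)
            distort = np.power(2.0, np.clip(rng.normal(0.0, 5.0, size=len(features)), -9, 9))
            total = mean.sum()
            mean = mean * distort
            if mean.sum() > 0:
                mean *= total / mean.sum()
        lam = np.clip(mean, 0.0, None)
        draws = np.zeros(len(features), dtype=np.int64)
        over = (lam > 0) & (alpha > 0)
        pois = (lam > 0) & (alpha <= 0)
        if over.any():
            n_param = 1.0 / alpha[over]
            draws[over] = rng.negative_binomial(n_param, n_param / (n_param + lam[over]))
        if pois.any():
            draws[pois] = rng.poisson(lam[pois])
        counts[lib] = draws
    return counts, s


@dataclass
class SimulationResult:
    fastq_paths: dict[str, Path]
    true_counts: pd.DataFrame     # features x libraries
    size_factors: pd.Series
    library_totals: pd.Series     # total reads written per library


def simulate_libraries(
    genome: dict[str, str],
    annotation: list[FeatureAnnotation],
    truth: SyntheticTruth,
    design: LibraryDesign,
    seed: int,
    outdir: str | Path,
) -> SimulationResult:
    """Write one FASTQ per library; returns paths and the exact truth.

    Reads are the mature feature sequence (with probability 0.1 shifted
    by one nucleotide at the 5' or 3' end), followed by the 3' adapter
    and random filler up to the machine length; qualities are high
    (>= 30) over the insert with a sub-20 decaying tail.  5% of reads are
    degradation fragments (random genome slices, 8-30 nt, the short end
    of which the length filter removes) and at least
    10 unique singleton sequences per library are planted.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, s = simulate_count_matrix(truth, design, seed)
    loci: dict[str, list[FeatureAnnotation]] = {}
    for f in annotation:
        if f.feature_id in truth.feature_expression.index:
            loci.setdefault(f.feature_id, []).append(f)

    chrom = next(iter(genome))
    gseq = genome[chrom]
    G = len(gseq)
    adapter = design.adapter
    mlen = design.machine_length
    tail = [17, 13, 9]  # sub-cutoff decaying 3' quality tail

    from .io import ReadRecord  # local import to avoid cycle at module load

    paths: dict[str, Path] = {}
    totals: dict[str, int] = {}
    for lib in design.libraries:
        rng = substream(seed, f"reads:{lib}")
        seqs: list[str] = []
        for fid in counts.index:
            c = int(counts.loc[fid, lib])
            if c == 0:
                continue
            flist = loci[fid]
            locus_idx = rng.integers(0, len(flist), size=c)
            do_offset = rng.random(size=c) < 0.1
            which_end = rng.integers(0, 2, size=c)  # 0: 5' end, 1: 3' end
            shift = rng.choice([-1, 1], size=c)
            for r in range(c):
                f = flist[int(locus_idx[r])]
                start, end = f.start, f.end
                if do_offset[r]:
                    # +/- 1 nt isomiR-style end offset, in read orientation
                    five = (which_end[r] == 0) == (f.strand == "+")
                    if five:
                        start = min(max(start + int(shift[r]), 0), end - 1)
                    else:
                        end = max(min(end + int(shift[r]), G), start + 1)
                insert = gseq[start:end]
                if f.strand == "-":
                    insert = _revcomp(insert)
                seqs.append(insert)
        n_features = len(seqs)
        n_deg = int(round(design.degradation_rate / (1 - design.degradation_rate) * n_features))
        for _ in range(n_deg):
            ln = int(rng.integers(8, 31))  # sub-15 fragments exercise the length filter
            st = int(rng.integers(0, G - ln))
            frag = gseq[st : st + ln]
            if rng.random() < 0.5:
                frag = _revcomp(frag)
            seqs.append(frag)
        for _ in range(design.n_singletons):
            seqs.append(_random_seq(rng, int(rng.integers(20, 26))))

        order = rng.permutation(len(seqs))
        records = []
        for ridx, i in enumerate(order, start=1):
            insert = seqs[int(i)]
            full = (insert + adapter)[:mlen]
            if len(full) < mlen:
                full += _random_seq(rng, mlen - len(full))
            nins = min(len(insert), mlen)
            q = np.empty(mlen, dtype=np.int16)
            q[:nins] = rng.integers(34, 41, size=nins)
            q[nins:] = 35
            q[-len(tail):] = tail
            records.append(ReadRecord(f"{lib}_r{ridx:06d}", full, q))
        path = outdir / f"{lib}.fastq"
        write_fastq(records, path)
        paths[lib] = path
        totals[lib] = len(records)
    return SimulationResult(paths, counts, s, pd.Series(totals))


# ---------------------------------------------------------------------------
# Interaction databases and gene tables
# ---------------------------------------------------------------------------

def make_interaction_databases(
    truth: SyntheticTruth,
    n_databases: int = 7,
    seed: int = 0,
    n_decoy_inverse: int = 30,
    n_decoy_same: int = 10,
    min_db_support: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Database-attributed interaction evidence with planted decoys.

    True target pairs get 3-7 supporting databases.  Inverse-direction
    decoy pairs (which would pass the expression filter) get only 1-2
    databases; same-direction decoys (blocked by the expression filter)
    get up to 7.  Returns ``(interactions, pair_info)`` where pair_info
    labels each pair as true/decoy for recovery tests.
    """
    if n_databases < min_db_support:
        import warnings

        warnings.warn(
            f"only {n_databases} databases but support threshold {min_db_support}: "
            "the voted network will be empty"
        )
    rng = substream(seed, "interactions")
    dbs = [f"db{i}" for i in range(1, n_databases + 1)]
    rows, info = [], []

    def add_pair(mirna: str, gene: str, support: int, kind: str) -> None:
        chosen = rng.choice(dbs, size=min(support, len(dbs)), replace=False)
        for db in sorted(chosen):
            rows.append({"mirna": mirna, "gene": gene, "database": db})
        info.append({"mirna": mirna, "gene": gene, "support": len(chosen), "kind": kind})

    mirnas = sorted(truth.true_targets)
    true_lo = min(min_db_support, n_databases)  # degenerate when dbs are scarce
    for mirna in mirnas:
        for gene in sorted(truth.true_targets[mirna]):
            add_pair(mirna, gene, int(rng.integers(true_lo, n_databases + 1)), "true")

    up_pool = sorted({g for m, gs in truth.true_targets.items()
                      if truth.spiked_log2fc.get(m, 0) < 0 for g in gs})
    down_pool = sorted({g for m, gs in truth.true_targets.items()
                        if truth.spiked_log2fc.get(m, 0) > 0 for g in gs})
    existing = {(m, g) for m, gs in truth.true_targets.items() for g in gs}
    attempts = 0
    made_inverse = made_same = 0
    while (made_inverse < n_decoy_inverse or made_same < n_decoy_same) and attempts < 10000:
        attempts += 1
        mirna = mirnas[int(rng.integers(0, len(mirnas)))] if mirnas else None
        if mirna is None:
            break
        down_mirna = truth.spiked_log2fc.get(mirna, 0) < 0
        want_same = made_same < n_decoy_same and (made_inverse >= n_decoy_inverse or rng.random() < 0.3)
        if want_same:
            pool = down_pool if down_mirna else up_pool  # same direction as miRNA
        else:
            pool = up_pool if down_mirna else down_pool  # inverse direction
        if not pool:
            continue
        gene = pool[int(rng.integers(0, len(pool)))]
        if (mirna, gene) in existing:
            continue
        existing.add((mirna, gene))
        if want_same:
            add_pair(mirna, gene, int(rng.integers(1, n_databases + 1)), "decoy_same_direction")
            made_same += 1
        else:
            add_pair(mirna, gene, int(rng.integers(1, min_db_support)), "decoy_low_support")
            made_inverse += 1

    interactions = pd.DataFrame(rows, columns=["mirna", "gene", "database"]).drop_duplicates()
    pair_info = pd.DataFrame(info, columns=["mirna", "gene", "support", "kind"])
    return interactions.reset_index(drop=True), pair_info


@dataclass
class GeneTables:
    up_genes: list[str]
    down_genes: list[str]
    go_map: pd.DataFrame   # columns: gene, term
    ppi: pd.DataFrame      # columns: geneA, geneB
    enriched_term: str

    def to_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"gene": self.up_genes}).to_csv(outdir / "up_genes.tsv", sep="\t", index=False)
        pd.DataFrame({"gene": self.down_genes}).to_csv(outdir / "down_genes.tsv", sep="\t", index=False)
        self.go_map.to_csv(outdir / "go_map.tsv", sep="\t", index=False)
        self.ppi.to_csv(outdir / "ppi.tsv", sep="\t", index=False)


def make_gene_tables(
    truth: SyntheticTruth,
    seed: int = 0,
    n_up: int = 100,
    n_down: int = 100,
    n_background: int = 300,
    n_terms: int = 20,
    enriched_term: str = "cell_motion",
    enriched_size: int = 20,
    enriched_in_list: int = 15,
) -> GeneTables:
    """DE gene lists, GO map and PPI edges consistent with the truth.

    All true targets of downregulated miRNAs are placed in the
    upregulated list (and vice versa); one GO term is enriched by
    construction (``enriched_in_list`` of its ``enriched_size`` members
    in the up list).
    """
    rng = substream(seed, "gene_tables")
    up = sorted({g for m, gs in truth.true_targets.items()
                 if truth.spiked_log2fc.get(m, 0) < 0 for g in gs})
    down = sorted({g for m, gs in truth.true_targets.items()
                   if truth.spiked_log2fc.get(m, 0) > 0 for g in gs})
    up += [f"UF{i:03d}" for i in range(1, max(0, n_up - len(up)) + 1)]
    down += [f"DF{i:03d}" for i in range(1, max(0, n_down - len(down)) + 1)]
    if set(up) & set(down):
        raise ValueError(f"up/down gene lists overlap: {sorted(set(up) & set(down))[:5]}")
    background = [f"BG{i:03d}" for i in range(1, n_background + 1)]
    universe = sorted(set(up) | set(down) | set(background))

    terms = [f"T{i:02d}" for i in range(1, n_terms + 1)] + [enriched_term]
    rows = []
    enriched_members = (
        list(rng.choice(up, size=min(enriched_in_list, len(up)), replace=False))
        + list(rng.choice(background, size=enriched_size - enriched_in_list, replace=False))
    )
    for g in enriched_members:
        rows.append({"gene": g, "term": enriched_term})
    plain_terms = terms[:-1]
    for g in universe:
        for t in rng.choice(plain_terms, size=int(rng.integers(1, 4)), replace=False):
            rows.append({"gene": g, "term": t})
    go_map = pd.DataFrame(rows, columns=["gene", "term"]).drop_duplicates().reset_index(drop=True)

    ppi_rows = []
    for i in range(len(enriched_members) - 1):  # connected backbone in the category
        ppi_rows.append({"geneA": enriched_members[i], "geneB": enriched_members[i + 1]})
    for _ in range(100):
        a, b = rng.choice(universe, size=2, replace=False)
        ppi_rows.append({"geneA": a, "geneB": b})
    ppi = pd.DataFrame(ppi_rows, columns=["geneA", "geneB"]).drop_duplicates().reset_index(drop=True)
    return GeneTables(up, down, go_map, ppi, enriched_term)
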