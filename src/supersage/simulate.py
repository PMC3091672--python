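"""Synthetic SuperSAGE data generator.

Emulates a five-library, two-time-point water-calcium challenge
experiment: a brackish-water control and a low-calcium challenge sampled
at 2 h and 12 h, plus a high-calcium challenge at 12 h only.  The
generator produces, from one seeded configuration,

* a transcript universe with a heavy-tailed (discretised log-normal)
  abundance law calibrated so that at the study's sequencing depth
  (~60,000-87,000 tags per library) roughly 70% of observed unitags are
  singletons;
* planted differentially expressed tags of the four decision-rule
  classes at known folds and directions, recorded in a truth table;
* reference DNA collections (curated cDNAs, predicted cDNAs and a genome
  that embeds every cDNA) plus a precomputed DNA-to-protein mapping
  table with E-values, orientations and GO terms;
* per-library ditag reads (linker + tag + reverse-complemented partner
  tag + linker) with injected duplicated ditags, truncated linkers,
  internal linker contamination, ambiguous bases and substitution
  errors at configured rates.

Everything downstream of sequencing is therefore testable against known
ground truth without any external data deposit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from ._util import ANCHOR, TAG_CORE_LEN, revcomp
from .matrix import TagCountMatrix

DE_CLASSES = (1, 2, 3, 4)

_DEFAULT_LINKERS = {
    "C2h": "ACCTGAGGAT",
    "LowCa2h": "GTTCAGCTCA",
    "C12h": "TGGAACCTTG",
    "HighCa12h": "CAAGTCGTGA",
    "LowCa12h": "GCTGTAACGG",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study conditions.

    ``library_depths`` default to the five observed library sizes; the
    abundance law (log-normal with shape 2.6 over 600,000 transcripts)
    is calibrated to the ~70%-singleton, ~39%-unitag regime at those
    depths.  Differentially expressed tags are planted on baselines in
    ``de_baseline_range`` (expected counts roughly 7-140 at paper depth,
    the range spanned by the study's strongest regulated tags), so a
    planted fold is in principle observable.  QC-corruption rates are
    chosen so that about 57% of sequenced reads survive quality control,
    matching the study's extraction yield.
    """

    library_names: tuple[str, ...] = ("C2h", "LowCa2h", "C12h", "HighCa12h", "LowCa12h")
    library_depths: tuple[int, ...] = (65378, 87388, 67996, 60142, 63471)
    n_transcripts: int = 600_000
    abundance_model: tuple[float, float] = (0.0, 2.6)  # log-normal (mu, sigma)
    de_fraction: float = 0.002
    de_fold_range: tuple[float, float] = (2.0, 16.0)
    de_baseline_range: tuple[float, float] = (1e-4, 2e-3)
    de_class_mix: tuple[float, float, float, float] = (0.4, 0.2, 0.2, 0.2)
    linker_sequences: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_LINKERS)
    )
    duplicate_ditag_rate: float = 0.55
    incomplete_linker_rate: float = 0.12
    contaminated_linker_rate: float = 0.05
    ambiguous_base_rate: float = 0.05
    sequencing_error_rate: float = 0.001
    antisense_fraction: float = 0.086
    unmappable_fraction: float = 0.35
    protein_fraction: float = 0.57
    dataset_mix: tuple[float, float, float] = (0.45, 0.20, 0.35)  # ncbi, ensembl, genome-only
    n_go_terms: int = 120
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts <= 0:
            raise ConfigurationError("n_transcripts must be positive")
        if len(self.library_depths) < len(self.library_names):
            raise ConfigurationError("fewer depths than libraries")
        if any(d <= 0 for d in self.library_depths):
            raise ConfigurationError("library depths must be positive")
        rates = (
            self.de_fraction,
            self.duplicate_ditag_rate,
            self.incomplete_linker_rate,
            self.contaminated_linker_rate,
            self.ambiguous_base_rate,
            self.sequencing_error_rate,
            self.antisense_fraction,
            self.unmappable_fraction,
            self.protein_fraction,
        )
        if any(not (0.0 <= r < 1.0) for r in rates):
            raise ConfigurationError("all rates must lie in [0, 1)")
        if self.de_fraction > 0 and self.de_fold_range[0] < 2:
            raise ConfigurationError(
                "de_fold_range minimum must be >= 2 when planting DE"
            )
        if abs(sum(self.de_class_mix) - 1.0) > 1e-9:
            raise ConfigurationError("de_class_mix must sum to 1")
        names = list(self.linker_sequences)
        for lib in self.library_names:
            if lib not in names:
                raise ConfigurationError(f"no linker for library {lib!r}")
        linkers = [self.linker_sequences[l] for l in self.library_names]
        if len(set(linkers)) != len(linkers):
            raise ConfigurationError("linkers must be mutually distinct")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Ground truth per simulated transcript/tag.

    One row per transcript: its tag (22-nt printed form), per-library
    expected frequency, planted DE class (0 = none) with fold and
    direction, mappability, dataset placement, antisense status and
    protein/GO assignment.
    """

    frame: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t", keep_default_na=False))


@dataclass
class ReferenceSet:
    """Three DNA collections plus the precomputed DNA->protein table."""

    ncbi_cdna: dict[str, str]
    ensembl_cdna: dict[str, str]
    genome: dict[str, str]
    blastx_table: pd.DataFrame

    def dataset(self, name: str) -> dict[str, str]:
        return {"ncbi_cdna": self.ncbi_cdna,
                "ensembl_cdna": self.ensembl_cdna,
                "genome": self.genome}[name]

    def write_fasta(self, name: str, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.dataset(name).items():
                fh.write(f">{sid}\n")
                for k in range(0, len(seq), 80):
                    fh.write(seq[k:k + 80] + "\n")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _random_tags(rng: np.random.Generator, n: int) -> np.ndarray:
    """n unique 22-nt tag cores containing no internal CATG."""
    out: list[str] = []
    seen: set[str] = set()
    need = n
    while need > 0:
        arr = _BASES[rng.integers(0, 4, (int(need * 1.15) + 8, TAG_CORE_LEN))]
        for row in arr:
            t = row.tobytes().decode()
            if ANCHOR in t or t in seen:
                continue
            seen.add(t)
            out.append(t)
            if len(out) == n:
                break
        need = n - len(out)
    return np.array(out, dtype=object)


def _rng_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------

def build_truth(config: SimulationConfig) -> TruthTable:
    """Deterministic ground truth shared by all generator outputs."""
    config.validate()
    rng = _rng_for(config, 0)
    n = config.n_transcripts
    libs = list(config.library_names)

    mu, sigma = config.abundance_model
    w = rng.lognormal(mu, sigma, n)
    p = w / w.sum()

    tags = _random_tags(rng, n)

    # plant DE on baselines drawn from the detectable range
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    de_class = np.zeros(n, dtype=int)
    fold = np.ones(n, dtype=float)
    direction = np.array([""] * n, dtype=object)
    affected_time = np.array([""] * n, dtype=object)
    if n_de:
        lo, hi = config.de_baseline_range
        p[de_idx] = np.exp(rng.uniform(np.log(lo), np.log(hi), n_de))
        p = p / p.sum()
        de_class[de_idx] = rng.choice(DE_CLASSES, size=n_de, p=list(config.de_class_mix))
        f_lo, f_hi = config.de_fold_range
        fold[de_idx] = rng.uniform(f_lo, f_hi, n_de)
        direction[de_idx] = np.where(rng.random(n_de) < 0.5, "up", "down")
        affected_time[de_idx[de_class[de_idx] == 2]] = rng.choice(
            ["2h", "12h"], size=int((de_class[de_idx] == 2).sum())
        )

    # per-library expected frequencies
    F = np.tile(p[:, None], (1, len(libs)))
    li = {name: k for k, name in enumerate(libs)}

    def bump(idx, lib_names):
        if len(idx) == 0:
            return
        eff = np.where(direction[idx] == "up", fold[idx], 1.0 / fold[idx])
        for lib in lib_names:
            if lib not in li:
                raise ConfigurationError(
                    f"DE planting requires a library named {lib!r}"
                )
            F[idx, li[lib]] = p[idx] * eff

    c1 = np.where(de_class == 1)[0]
    bump(c1, ["LowCa2h", "LowCa12h"])
    c2 = np.where(de_class == 2)[0]
    c2_2h = c2[affected_time[c2] == "2h"]
    c2_12h = c2[affected_time[c2] == "12h"]
    bump(c2_2h, ["LowCa2h"])
    bump(c2_12h, ["LowCa12h"])
    c3 = np.where(de_class == 3)[0]
    bump(c3, ["HighCa12h"])
    c4 = np.where(de_class == 4)[0]
    bump(c4, ["LowCa12h", "HighCa12h"])
    F = F / F.sum(axis=0, keepdims=True)

    # mappability, antisense, dataset placement, protein/GO assignment
    unmappable = rng.random(n) < config.unmappable_fraction
    antisense = (~unmappable) & (rng.random(n) < config.antisense_fraction)
    dataset = np.array(["none"] * n, dtype=object)
    mappable_idx = np.where(~unmappable)[0]
    dataset[mappable_idx] = rng.choice(
        ["ncbi_cdna", "ensembl_cdna", "genome"],
        size=len(mappable_idx),
        p=list(config.dataset_mix),
    )
    has_protein = (~unmappable) & (rng.random(n) < config.protein_fraction)
    protein_id = np.array([""] * n, dtype=object)
    gene_symbol = np.array([""] * n, dtype=object)
    evalue = np.full(n, np.nan)
    go_terms = np.array([""] * n, dtype=object)
    prot_idx = np.where(has_protein)[0]
    if len(prot_idx):
        protein_id[prot_idx] = [f"P{k:06d}" for k in prot_idx]
        gene_symbol[prot_idx] = [f"gene{k:06d}" for k in prot_idx]
        evalue[prot_idx] = 10.0 ** rng.uniform(-40.0, -6.0, len(prot_idx))
        vocab = [f"GO:{k + 1:07d}" for k in range(config.n_go_terms)]
        n_terms = rng.integers(1, 5, len(prot_idx))
        go_terms[prot_idx] = [
            ";".join(sorted(rng.choice(vocab, size=k, replace=False)))
            for k in n_terms
        ]

    frame = pd.DataFrame(
        {
            "transcript_id": [f"T{k:06d}" for k in range(n)],
            "tag": tags,
            "de_class": de_class,
            "fold": fold,
            "direction": direction,
            "affected_time": affected_time,
            "unmappable": unmappable,
            "antisense": antisense,
            "dataset": dataset,
            "protein_id": protein_id,
            "gene_symbol": gene_symbol,
            "evalue": evalue,
            "go_terms": go_terms,
        }
    )
    for k, lib in enumerate(libs):
        frame[f"freq_{lib}"] = F[:, k]
    return TruthTable(frame)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_count_matrix(
    config: SimulationConfig, truth: TruthTable | None = None
) -> tuple[TagCountMatrix, TruthTable]:
    """Multinomial tag counts per library under the truth's frequencies.

    Only tags observed in at least one library appear in the matrix; the
    truth table keeps every simulated transcript.
    """
    if truth is None:
        truth = build_truth(config)
    rng = _rng_for(config, 1)
    libs = list(config.library_names)
    F = truth.frame[[f"freq_{lib}" for lib in libs]].to_numpy()
    counts = np.stack(
        [
            rng.multinomial(int(config.library_depths[k]), F[:, k])
            for k in range(len(libs))
        ],
        axis=1,
    )
    observed = counts.sum(axis=1) > 0
    df = pd.DataFrame(
        counts[observed], index=truth.frame["tag"].to_numpy()[observed], columns=libs
    )
    return TagCountMatrix(df), truth


def generate_reference(
    config: SimulationConfig, truth: TruthTable | None = None
) -> tuple[ReferenceSet, TruthTable]:
    """Reference DNA datasets and the DNA->protein table for the truth.

    Every mappable transcript gets a cDNA-like sequence ending in its
    26-nt tag (the tag's CATG is the 3'-most anchor site); antisense
    transcripts are stored reverse-complemented so their tag maps to the
    minus strand of a sense cDNA.  The genome embeds every cDNA between
    random flanks, exercising the dataset hierarchy; genome-only
    transcripts occur in no cDNA set.  The mapping table carries one row
    per protein-bearing DNA, keyed by cDNA id or, for genome-only
    transcripts, by the strand-aware 1000-bp upstream-fragment id
    "chrom:start-end:strand".
    """
    if truth is None:
        truth = build_truth(config)
    rng = _rng_for(config, 2)
    tf = truth.frame

    mappable = tf.index[~tf["unmappable"]].to_numpy()
    ncbi: dict[str, str] = {}
    ensembl: dict[str, str] = {}
    stored_seq: dict[int, str] = {}
    tag_pos: dict[int, tuple[int, str]] = {}  # idx -> (pos in stored seq, strand)
    for idx in mappable:
        tag26 = ANCHOR + tf.at[idx, "tag"]
        prefix = _random_dna(rng, int(rng.integers(80, 300)))
        transcript = prefix + tag26
        if tf.at[idx, "antisense"]:
            seq = revcomp(transcript)
            pos, strand = 0, "-"
        else:
            seq = transcript
            pos, strand = len(prefix), "+"
        stored_seq[idx] = seq
        tag_pos[idx] = (pos, strand)
        cdna_id = f"cdna_{tf.at[idx, 'transcript_id']}"
        ds = tf.at[idx, "dataset"]
        if ds == "ncbi_cdna":
            ncbi[cdna_id] = seq
        elif ds == "ensembl_cdna":
            ensembl[cdna_id] = seq

    # assemble the genome: all stored sequences over ~21 chromosomes
    n_chrom = min(21, max(1, len(mappable)))
    genome: dict[str, str] = {}
    genome_loc: dict[int, tuple[str, int]] = {}  # idx -> (chrom, offset of seq)
    order = rng.permutation(mappable)
    chunks = np.array_split(order, n_chrom)
    for c, chunk in enumerate(chunks):
        name = f"chr{c + 1}"
        parts: list[str] = []
        at = 0
        for idx in chunk:
            flank = _random_dna(rng, int(rng.integers(50, 200)))
            parts.append(flank)
            at += len(flank)
            genome_loc[idx] = (name, at)
            parts.append(stored_seq[idx])
            at += len(stored_seq[idx])
        parts.append(_random_dna(rng, int(rng.integers(50, 200))))
        genome[name] = "".join(parts)

    rows = []
    for idx in mappable:
        if not tf.at[idx, "protein_id"]:
            continue
        ds = tf.at[idx, "dataset"]
        if ds in ("ncbi_cdna", "ensembl_cdna"):
            dna_id = f"cdna_{tf.at[idx, 'transcript_id']}"
        else:
            chrom, off = genome_loc[idx]
            pos, strand = tag_pos[idx]
            s = off + pos
            e = s + len(ANCHOR) + TAG_CORE_LEN
            if strand == "+":
                a, b = max(0, s - 1000), s
            else:
                a, b = e, min(len(genome[chrom]), e + 1000)
            dna_id = f"{chrom}:{a}-{b}:{strand}"
        rows.append(
            {
                "dna_id": dna_id,
                "dataset": ds,
                "protein_id": tf.at[idx, "protein_id"],
                "evalue": tf.at[idx, "evalue"],
                "protein_orientation": "+",
                "gene_symbol": tf.at[idx, "gene_symbol"],
                "go_terms": tf.at[idx, "go_terms"],
            }
        )
    blastx = pd.DataFrame(
        rows,
        columns=[
            "dna_id", "dataset", "protein_id", "evalue",
            "protein_orientation", "gene_symbol", "go_terms",
        ],
    )
    return ReferenceSet(ncbi, ensembl, genome, blastx), truth


@dataclass
class SimulatedRead:
    read_id: str
    library: str
    sequence: str
    truth_qc: str  # pass | duplicate | incomplete_linker | internal_linker | ambiguous_base


def generate_ditag_reads(
    config: SimulationConfig, matrix: TagCountMatrix
) -> list[SimulatedRead]:
    """Per-library ditag reads reproducing ``matrix`` plus QC-doomed extras.

    A clean read is linker + tagA + revcomp(tagB) + linker, with tags
    paired uniformly within the library and pairings adjusted so no two
    clean ditags are byte-identical (an odd leftover tag is emitted as a
    single-tag read).  Corrupted reads are appended on top of the clean
    stream at the configured rates, each flagged with the QC class that
    should reject it, so that extraction of the QC-passing reads
    reproduces the input matrix whenever the substitution-error rate is
    zero.
    """
    for lib in matrix.libraries:
        if lib not in config.linker_sequences:
            raise ConfigurationError(f"no linker configured for library {lib!r}")
    rng = _rng_for(config, 3)
    reads: list[SimulatedRead] = []

    for lib in matrix.libraries:
        linker = config.linker_sequences[lib]
        col = matrix.counts[lib]
        tags26 = [ANCHOR + t for t, c in col.items() for _ in range(int(c))]
        tags26 = list(np.array(tags26, dtype=object)[rng.permutation(len(tags26))])
        leftover = tags26.pop() if len(tags26) % 2 else None
        a = tags26[0::2]
        b = tags26[1::2]
        linker_set = list(config.linker_sequences.values())

        def has_linker(ditag: str) -> bool:
            return any(lk in ditag for lk in linker_set)

        # Repair pairings so no two clean ditags are byte-identical (which
        # QC would deduplicate) and no ditag interior contains a linker
        # (which QC would reject): swap partners of offending pairs with
        # random other pairs.  Resolvable whenever tag diversity suffices;
        # any residue is realistic duplicate loss.
        n_pairs = len(a)
        for _ in range(200):
            seqs = [x + revcomp(y) for x, y in zip(a, b)]
            seen: dict[str, int] = {}
            bad = []
            for k, s in enumerate(seqs):
                if has_linker(s):
                    bad.append(k)
                elif s in seen:
                    bad.append(k)
                else:
                    seen[s] = k
            if not bad or n_pairs < 2:
                break
            for k in bad:
                j = int(rng.integers(0, n_pairs))
                b[k], b[j] = b[j], b[k]

        ditags = [x + revcomp(y) for x, y in zip(a, b)]
        if leftover is not None:
            ditags.append(leftover)

        clean = [linker + d + linker for d in ditags]
        if config.sequencing_error_rate > 0:
            clean = [_mutate(rng, s, config.sequencing_error_rate) for s in clean]
        k0 = len(reads)
        for j, s in enumerate(clean):
            reads.append(SimulatedRead(f"{lib}_r{k0 + j:07d}", lib, s, "pass"))

        n_clean = len(clean)
        lk = len(linker)

        def pick() -> str:
            return clean[int(rng.integers(0, n_clean))]

        extras: list[tuple[str, str]] = []
        for _ in range(int(round(config.duplicate_ditag_rate * n_clean))):
            extras.append((pick(), "duplicate"))
        for _ in range(int(round(config.incomplete_linker_rate * n_clean))):
            cut = int(rng.integers(1, lk + 1))
            extras.append((pick()[cut:], "incomplete_linker"))
        for _ in range(int(round(config.contaminated_linker_rate * n_clean))):
            s = pick()
            pos = int(rng.integers(lk + 2, max(lk + 3, len(s) - lk - 2)))
            extras.append((s[:pos] + linker + s[pos:], "internal_linker"))
        for _ in range(int(round(config.ambiguous_base_rate * n_clean))):
            s = list(pick())
            for pos in rng.integers(lk, len(s) - lk, int(rng.integers(1, 4))):
                s[int(pos)] = "N"
            extras.append(("".join(s), "ambiguous_base"))

        k0 = len(reads)
        for j, (s, flag) in enumerate(extras):
            reads.append(SimulatedRead(f"{lib}_x{k0 + j:07d}", lib, s, flag))
    return reads


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    s = list(seq)
    for pos in rng.integers(0, len(s), k):
        cur = s[int(pos)]
        alt = "ACGT".replace(cur, "") or "ACGT"
        s[int(pos)] = alt[int(rng.integers(0, len(alt)))]
    return "".join(s)


def reads_to_fasta(reads: Iterable[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")
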