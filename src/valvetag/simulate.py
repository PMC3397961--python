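"""Synthetic data generator for the full pipeline.

Emulates the study design the pipeline expects: a handful of
replicate-free tissue libraries of 21-bp NlaIII-anchored tags with
negative-binomial count noise at a fixed dispersion, a subset of genes
enriched in the valve-forming-region libraries, 1-bp sequencing-error
satellite tags, Chastity-style quality failures, ChIP coverage with
planted peaks over a Poisson background, and qPCR cycle-threshold tables.
Every output is accompanied by a machine-readable truth table so recovery
can be scored exactly.

All randomness flows from ``SyntheticConfig.seed``; each output stream
draws from its own deterministically derived child generator, so the same
configuration produces byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

TAG_LEN = 21
ANCHOR = "CATG"
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    The five default library roles mirror a regional dissection design:
    two valve-forming regions (``avc``, ``oft``), two chamber controls
    (``atria``, ``ventricles``) and one mutant valve library
    (``avc_null``) in which a fraction of the valve-enriched genes lose
    their enrichment.
    """

    n_genes: int = 2000
    library_roles: tuple[str, ...] = ("avc", "oft", "atria", "ventricles", "avc_null")
    valve_roles: tuple[str, ...] = ("avc", "oft", "avc_null")
    library_depth: int = 5_000_000
    dispersion: float = 0.12
    base_tpm: float = 10.0
    frac_enriched: float = 0.1
    log2fc_enriched: float = 2.0
    frac_null_responsive: float = 0.5
    seq_error_rate: float = 0.001
    chastity_fail_rate: float = 0.2
    shared_tag_fraction: float = 0.0
    read_length: int = 36
    transcript_length: int = 300
    gene_spacing: int = 5000
    chip_background_rate: float = 3.0
    n_peaks: int = 50
    peak_amplitude: float = 40.0
    peak_halfwidth: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for name in ("frac_enriched", "seq_error_rate", "chastity_fail_rate",
                     "shared_tag_fraction", "frac_null_responsive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < TAG_LEN:
            raise ValueError(f"read_length must be >= {TAG_LEN}")
        if self.transcript_length < TAG_LEN:
            raise ValueError("impossible geometry: transcript shorter than a tag")

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for a named output stream, derived from the seed."""
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))


@dataclass
class Transcriptome:
    """Synthetic transcript sequences plus gene annotation.

    ``tags`` records the 3'-most virtual tag of each gene — the ground
    truth the tag pipeline should recover.
    """

    sequences: dict[str, str]
    annotation: pd.DataFrame  # gene_id, chrom, strand, tss
    tags: pd.DataFrame        # gene_id, tag
    chrom_lengths: dict[str, int]


@dataclass
class TruthTable:
    """Ground truth: per-gene expected TPM per role and enrichment flags."""

    genes: pd.DataFrame            # indexed by gene_id
    peaks: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def enriched_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["enriched"]])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _strip_anchor(seq: str, rng: np.random.Generator) -> str:
    """Replace any CATG occurrence so a region carries no anchor site."""
    while ANCHOR in seq:
        i = seq.index(ANCHOR)
        seq = seq[:i] + _random_seq(rng, 4) + seq[i + 4:]
    return seq


def simulate_transcriptome(config: SyntheticConfig) -> Transcriptome:
    """Build one transcript per gene with a well-defined 3'-most tag.

    Each transcript ends with ``<prefix> CATG <17-mer> <anchor-free tail>``
    so its 3'-most NlaIII tag is fully determined.  A configurable
    fraction of genes deliberately share an identical 3'-most tag to
    exercise ambiguity handling downstream.
    """
    rng = config.rng("transcriptome")
    n = config.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]

    # unique 17-mers downstream of the anchor; rejection-sample collisions
    seen: set[str] = set()
    cores: list[str] = []
    while len(cores) < n:
        c = _random_seq(rng, TAG_LEN - 4)
        if c not in seen:
            seen.add(c)
            cores.append(c)

    # designated pairs share one tag
    n_shared_genes = int(round(config.shared_tag_fraction * n / 2)) * 2
    for k in range(0, n_shared_genes, 2):
        cores[k + 1] = cores[k]

    tail_len = 25
    prefix_len = max(0, config.transcript_length - TAG_LEN - tail_len)
    sequences, tags = {}, []
    for gid, core in zip(gene_ids, cores):
        prefix = _random_seq(rng, prefix_len)
        tail = _strip_anchor(_random_seq(rng, tail_len), rng)
        # the tail must not recreate an anchor across the junction
        while ANCHOR in (core[-3:] + tail[:3]):
            tail = _strip_anchor(_random_seq(rng, tail_len), rng)
        sequences[gid] = prefix + ANCHOR + core + tail
        tags.append(ANCHOR + core)

    spacing = config.gene_spacing
    chrom = "chr1"
    strands = rng.choice(np.array(["+", "-"]), size=n, p=[0.5, 0.5])
    tss = (np.arange(n) * spacing + spacing // 2).astype(int)
    annotation = pd.DataFrame(
        {"gene_id": gene_ids, "chrom": chrom, "strand": strands, "tss": tss}
    )
    return Transcriptome(
        sequences=sequences,
        annotation=annotation,
        tags=pd.DataFrame({"gene_id": gene_ids, "tag": tags}),
        chrom_lengths={chrom: int(n * spacing)},
    )


def make_truth(config: SyntheticConfig, transcriptome: Transcriptome) -> TruthTable:
    """Assign expected TPM per library role and flag enriched genes.

    Every gene expresses at ``base_tpm`` in every role; a fraction
    ``frac_enriched`` is multiplied by ``2**log2fc_enriched`` in the
    valve-role libraries.  In the mutant library (``avc_null``) a
    fraction ``frac_null_responsive`` of the enriched genes reverts to
    baseline, modelling loss of the upstream activator.
    """
    rng = config.rng("truth")
    gene_ids = transcriptome.tags["gene_id"].tolist()
    n = len(gene_ids)
    n_enr = int(round(config.frac_enriched * n))
    enriched_idx = rng.choice(n, size=n_enr, replace=False)
    enriched = np.zeros(n, dtype=bool)
    enriched[enriched_idx] = True
    responsive = np.zeros(n, dtype=bool)
    n_resp = int(round(config.frac_null_responsive * n_enr))
    if n_resp:
        responsive[rng.choice(enriched_idx, size=n_resp, replace=False)] = True

    fc = 2.0 ** config.log2fc_enriched
    genes = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    genes["enriched"] = enriched
    genes["null_responsive"] = responsive
    for role in config.library_roles:
        tpm = np.full(n, config.base_tpm)
        if role in config.valve_roles:
            tpm[enriched] *= fc
        if role == "avc_null":
            tpm[responsive] = config.base_tpm
        genes[f"tpm_{role}"] = tpm
    return TruthTable(genes=genes)


def simulate_counts(config: SyntheticConfig, truth: TruthTable) -> pd.DataFrame:
    """Draw per-gene per-library counts from NB(mean, dispersion).

    mean = expected_TPM x depth / 1e6; variance = mean + dispersion x mean^2.
    A dispersion of 0 is accepted as the Poisson limit.
    """
    rng = config.rng("counts")
    out = {}
    phi = config.dispersion
    for role in config.library_roles:
        mu = truth.genes[f"tpm_{role}"].to_numpy() * config.library_depth / 1e6
        out[role] = _nb_draw(rng, mu, phi)
    return pd.DataFrame(out, index=truth.genes.index)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    counts = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if phi == 0:
        counts[pos] = rng.poisson(mu[pos])
    else:
        r = 1.0 / phi
        p = r / (r + mu[pos])
        counts[pos] = rng.negative_binomial(r, p)
    return counts


def simulate_reads(
    counts: pd.Series | dict,
    transcriptome: Transcriptome,
    config: SyntheticConfig,
    library: str,
    path,
) -> dict:
    """Write a FASTQ library: one read per count unit of each gene's tag.

    The first 21 bases of each read are the gene's 3'-most virtual tag,
    with per-base substitutions at ``seq_error_rate``; the rest is filler
    up to ``read_length``.  On top of the good reads, quality-failure
    reads are added so that they make up ``chastity_fail_rate`` of the
    library; they carry the Illumina filter flag (``1:Y:0:0``) and low
    quality characters.  Returns a small QC dict.
    """
    counts = pd.Series(counts)
    rng = config.rng(f"reads:{library}")
    tag_of = dict(zip(transcriptome.tags["gene_id"], transcriptome.tags["tag"]))

    genes = [g for g in counts.index if counts[g] > 0]
    n_good = int(sum(int(counts[g]) for g in genes))
    tag_rows = np.empty((n_good, TAG_LEN), dtype="S1")
    pos = 0
    for g in genes:
        c = int(counts[g])
        row = np.frombuffer(tag_of[g].encode(), dtype="S1")
        tag_rows[pos : pos + c] = row
        pos += c

    # per-base substitution errors in the tag region
    if config.seq_error_rate > 0 and n_good:
        err = rng.random(tag_rows.shape) < config.seq_error_rate
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err)
            idx = np.searchsorted(
                _BASES, tag_rows[err]
            )  # ACGT are sorted, so index == base code
            tag_rows[err] = _BASES[(idx + shift) % 4]

    f = config.chastity_fail_rate
    n_fail = int(round(n_good * f / (1.0 - f))) if f < 1.0 else 0
    fail_pick = rng.integers(0, max(len(genes), 1), size=n_fail) if genes else []
    filler_len = config.read_length - TAG_LEN

    order = rng.permutation(n_good + n_fail)
    good_qual = "I" * config.read_length
    fail_qual = "#" * config.read_length
    with open(path, "w") as fh:
        for k, slot in enumerate(order):
            if slot < n_good:
                tag = tag_rows[slot].tobytes().decode()
                flag, qual = "N", good_qual
            else:
                tag = tag_of[genes[fail_pick[slot - n_good]]] if genes else ANCHOR + "A" * 17
                flag, qual = "Y", fail_qual
            filler = _random_seq(rng, filler_len)
            fh.write(f"@sim:{library}:{k} 1:{flag}:0:0\n{tag}{filler}\n+\n{qual}\n")
    return {"library": library, "n_good": n_good, "n_fail": n_fail,
            "n_total": n_good + n_fail}


def simulate_chip(
    config: SyntheticConfig,
    transcriptome: Transcriptome,
    truth: TruthTable,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], pd.DataFrame]:
    """Simulate ChIP and input-control coverage with planted peaks.

    Control coverage is Poisson(``chip_background_rate``) per base; ChIP
    coverage is an independent Poisson background plus triangular bumps
    of height ``peak_amplitude`` at summits placed near the TSS of
    selected target genes (enriched genes first).  Returns (chip,
    control, truth-peaks table).
    """
    rng = config.rng("chip")
    chrom_lengths = transcriptome.chrom_lengths
    control = {c: rng.poisson(config.chip_background_rate, L).astype(float)
               for c, L in chrom_lengths.items()}
    chip = {c: rng.poisson(config.chip_background_rate, L).astype(float)
            for c, L in chrom_lengths.items()}

    ann = transcriptome.annotation.set_index("gene_id")
    enriched = truth.enriched_genes
    pool = enriched if len(enriched) >= config.n_peaks else list(ann.index)
    targets = list(rng.choice(pool, size=min(config.n_peaks, len(pool)), replace=False))

    hw = config.peak_halfwidth
    rows = []
    for gid in targets:
        chrom = ann.at[gid, "chrom"]
        L = chrom_lengths[chrom]
        summit = int(np.clip(ann.at[gid, "tss"] + rng.integers(-500, 501), hw, L - hw - 1))
        x = np.arange(summit - hw, summit + hw + 1)
        bump = np.round(config.peak_amplitude * (1.0 - np.abs(x - summit) / hw))
        chip[chrom][x] += bump
        rows.append({"chrom": chrom, "start": summit - hw, "end": summit + hw + 1,
                     "summit": summit, "amplitude": config.peak_amplitude,
                     "gene_id": gid})
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit",
                                        "amplitude", "gene_id"])
    return chip, control, peaks


def simulate_qpcr(
    true_enrichments: dict[str, float] | Sequence[float],
    config: SyntheticConfig,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    base_ct: float = 28.0,
) -> pd.DataFrame:
    """Emit a cycle-threshold table whose ΔcT encodes known enrichments.

    cT_igg − cT_antibody = log2(enrichment) + Gaussian noise.
    """
    if not isinstance(true_enrichments, dict):
        true_enrichments = {f"target{i}": v for i, v in enumerate(true_enrichments)}
    if any(v <= 0 for v in true_enrichments.values()):
        raise ValueError("enrichments must be positive")
    rng = config.rng("qpcr")
    rows = []
    for rep in range(1, n_replicates + 1):
        for target, e in true_enrichments.items():
            dct = np.log2(e) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"target": target, "replicate": rep,
                         "ct_igg": base_ct, "ct_antibody": base_ct - dct})
    return pd.DataFrame(rows)


def default_config(**overrides) -> SyntheticConfig:
    return replace(SyntheticConfig(), **overrides)
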