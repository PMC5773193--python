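"""Synthetic mosaic F0 cohorts with exact ground truth.

Injected F0 embryos are genetic mosaics: editing during the first
cleavage divisions produces a small number of founder alleles per animal
whose frequencies vary widely between animals.  The generator emulates
the salient features of real amplicon data from such cohorts:

* per-animal editing rates drawn from a Beta distribution, giving the
  broad 0-100% inter-animal spread of mutagenesis rates;
* a small founder-allele pool per animal (default 4) with Dirichlet
  frequencies;
* deletion-biased indel spectra (default 80% deletions) with a
  recurrent, locus-specific "MMEJ" deletion whose per-animal weight is
  Beta-distributed over roughly 0-0.78;
* Illumina-like i.i.d. single-nucleotide substitution errors (default
  2e-3 per base) that never introduce indels.

Every animal's exact expected fractions (q, fs, im, nm) and biallelic
loss-of-function probabilities are computed from the allele pool, so the
whole pipeline — alignment, event calling, classification,
quantification and the probability model — can be tested for parameter
recovery without any external data.  Allele categories are obtained by
running the classifier on the error-free allele sequences, so truth and
pipeline share one definition of "mutated".

What the generator does not emulate: PCR duplicates and chimeras,
quality-score structure, paired-end artefacts, and large deletions
spanning two quantification windows (each founder allele receives at
most one indel per target).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicons import Amplicon, SgRNATarget, cleavage_site, validate_target
from .classify import (
    MutationEvent,
    ReadRecord,
    TargetCall,
    classify_read,
    make_aligner,
)
from .lof import POOLED_SCOPE, p_fs, p_mut

__all__ = [
    "TargetSimConfig",
    "SimulationConfig",
    "Allele",
    "AllelePool",
    "SimulatedCohort",
    "simulate_allele_pool",
    "simulate_reads",
    "simulate_cohort",
    "expected_lof",
    "demo_panel",
    "write_panel",
    "write_fastq_gz",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TargetSimConfig:
    """Generative parameters for one sgRNA target.

    ``editing_rate`` fixes the per-animal editing probability θ; when
    ``None`` θ is drawn per animal from ``Beta(*editing_beta)``.  The
    recurrent deletion (``mmej_size`` nt at a fixed position straddling
    the cut) is chosen with a per-animal weight drawn as
    ``mmej_weight_scale * Beta(*mmej_weight_beta)``; all other indels
    draw a deletion with probability ``deletion_prob``, sizes from
    truncated geometric distributions.
    """

    editing_rate: float | None = None
    editing_beta: tuple[float, float] = (5.0, 2.0)
    deletion_prob: float = 0.8
    deletion_size_p: float = 0.25
    max_deletion: int = 30
    insertion_size_p: float = 0.7
    max_insertion: int = 10
    mmej_size: int = 6
    mmej_weight_beta: tuple[float, float] = (0.7, 1.3)
    mmej_weight_scale: float = 0.78
    n_founder_alleles: int = 4
    dirichlet_alpha: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generative parameters."""

    seed: int
    n_animals: int = 96
    #: sequencing depth per animal and amplicon
    reads_per_animal: int = 2000
    #: i.i.d. substitution error probability per sequenced base
    substitution_rate: float = 0.002
    #: per-target overrides; targets not listed use TargetSimConfig()
    targets: Mapping[str, TargetSimConfig] = field(default_factory=dict)

    def target_config(self, target_id: str) -> TargetSimConfig:
        return self.targets.get(target_id, TargetSimConfig())


@dataclass(frozen=True)
class Allele:
    """One founder allele: its sequence, generative edits and frequency."""

    sequence: str
    #: target_id -> planted indel (absent entry = wildtype at that target)
    events: dict[str, MutationEvent]
    frequency: float
    #: target_id -> classifier call on the error-free sequence
    calls: dict[str, TargetCall]


@dataclass(frozen=True)
class AllelePool:
    """All founder alleles of one animal on one amplicon, with exact truth."""

    animal_id: str
    amplicon_id: str
    alleles: tuple[Allele, ...]
    #: target_id -> per-animal editing rate used
    theta: dict[str, float]
    #: target_id -> exact expected (q, fs, im, nm)
    truth: dict[str, tuple[float, float, float, float]]


def _truncated_geometric(rng: np.random.Generator, p: float, maximum: int) -> int:
    size = int(rng.geometric(p))
    while size > maximum:
        size = int(rng.geometric(p))
    return size


def _recurrent_deletion(target: SgRNATarget, size: int) -> MutationEvent:
    c = cleavage_site(target)
    return MutationEvent("deletion", c - size // 2, size)


def _draw_indel(
    rng: np.random.Generator,
    target: SgRNATarget,
    amplicon: Amplicon,
    cfg: TargetSimConfig,
    mmej_weight: float,
) -> MutationEvent:
    c = cleavage_site(target)
    if rng.random() < mmej_weight:
        return _recurrent_deletion(target, cfg.mmej_size)
    if rng.random() < cfg.deletion_prob:
        size = _truncated_geometric(rng, cfg.deletion_size_p, cfg.max_deletion)
        start = c - int(rng.integers(0, size + 1))  # any placement across the cut
        start = max(0, min(start, len(amplicon) - size))
        return MutationEvent("deletion", start, size)
    size = _truncated_geometric(rng, cfg.insertion_size_p, cfg.max_insertion)
    alt = "".join("ACGT"[i] for i in rng.integers(0, 4, size))
    return MutationEvent("insertion", c, size, alt)


def _apply_events(sequence: str, events: Iterable[MutationEvent]) -> str:
    """Apply indels to a reference sequence (right-to-left, so earlier
    coordinates stay valid)."""
    seq = sequence
    for ev in sorted(events, key=lambda e: e.ref_start, reverse=True):
        if ev.kind == "deletion":
            seq = seq[: ev.ref_start] + seq[ev.ref_start + ev.length :]
        elif ev.kind == "insertion":
            seq = seq[: ev.ref_start] + ev.alt + seq[ev.ref_start :]
        else:
            raise ValueError("allele edits must be indels")
    return seq


def simulate_allele_pool(
    config: SimulationConfig,
    targets: SgRNATarget | Sequence[SgRNATarget],
    amplicon: Amplicon,
    rng: np.random.Generator,
    animal_id: str = "animal",
) -> AllelePool:
    """Draw one animal's founder-allele pool for one amplicon.

    Each founder allele is edited independently at every target on the
    amplicon with the animal's per-target editing rate θ; edited targets
    receive either the recurrent locus-specific deletion (with the
    animal's MMEJ weight) or a random indel at the cut.  Dirichlet
    frequencies are assigned to the founders and exact expected fractions
    are computed by classifying each error-free allele sequence.
    """
    if isinstance(targets, SgRNATarget):
        targets = [targets]
    targets = [validate_target(t, amplicon) for t in targets]

    theta: dict[str, float] = {}
    mmej_w: dict[str, float] = {}
    for t in targets:
        cfg = config.target_config(t.target_id)
        if cfg.editing_rate is not None:
            theta[t.target_id] = float(cfg.editing_rate)
        else:
            theta[t.target_id] = float(rng.beta(*cfg.editing_beta))
        mmej_w[t.target_id] = float(
            cfg.mmej_weight_scale * rng.beta(*cfg.mmej_weight_beta)
        )

    cfg0 = config.target_config(targets[0].target_id)
    k = cfg0.n_founder_alleles
    founders: list[dict[str, MutationEvent]] = []
    for _ in range(k):
        events: dict[str, MutationEvent] = {}
        for t in targets:
            cfg = config.target_config(t.target_id)
            if rng.random() < theta[t.target_id]:
                events[t.target_id] = _draw_indel(
                    rng, t, amplicon, cfg, mmej_w[t.target_id]
                )
        founders.append(events)
    frequencies = rng.dirichlet([cfg0.dirichlet_alpha] * k)

    # merge founders with identical sequence and classify once
    aligner = make_aligner()
    merged: dict[str, Allele] = {}
    for events, freq in zip(founders, frequencies):
        seq = _apply_events(amplicon.sequence, events.values())
        if seq in merged:
            old = merged[seq]
            merged[seq] = Allele(seq, old.events, old.frequency + freq, old.calls)
            continue
        rc = classify_read(ReadRecord("allele", seq), amplicon, targets, aligner)
        assert rc is not None, "error-free allele must align"
        merged[seq] = Allele(seq, events, float(freq), rc.calls)
    alleles = tuple(merged.values())

    truth: dict[str, tuple[float, float, float, float]] = {}
    for t in targets:
        q = fs = im = nm = 0.0
        for al in alleles:
            call = al.calls[t.target_id]
            if call.status == "unmodified":
                q += al.frequency
            elif call.category == "frameshift":
                fs += al.frequency
            elif call.category == "inframe":
                im += al.frequency
            else:
                nm += al.frequency
        truth[t.target_id] = (q, fs, im, nm)

    return AllelePool(
        animal_id=animal_id,
        amplicon_id=amplicon.amplicon_id,
        alleles=alleles,
        theta=theta,
        truth=truth,
    )


def _add_substitution_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    # replace with one of the three other bases, never an indel
    idx = np.searchsorted(_BASES, arr[hits])
    arr[hits] = _BASES[(idx + rng.integers(1, 4, hits.size)) % 4]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    pool: AllelePool,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_reads: int | None = None,
) -> list[ReadRecord]:
    """Sample reads from an allele pool with substitution errors.

    Each read picks a founder allele by frequency and receives i.i.d.
    substitution errors at ``config.substitution_rate`` per base; errors
    never create indels.  Qualities are constant Q40.
    """
    if n_reads is None:
        n_reads = config.reads_per_animal
    freqs = np.array([al.frequency for al in pool.alleles])
    freqs = freqs / freqs.sum()
    choices = rng.choice(len(pool.alleles), size=n_reads, p=freqs)
    reads = []
    for i, ai in enumerate(choices):
        seq = _add_substitution_errors(
            pool.alleles[ai].sequence, config.substitution_rate, rng
        )
        reads.append(
            ReadRecord(
                read_id=f"{pool.animal_id}:{pool.amplicon_id}:{i}",
                sequence=seq,
            )
        )
    return reads


def expected_lof(
    truth_by_target: Mapping[str, tuple[float, float, float, float]],
    panel: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Exact pooled (p_mut, p_fs) from truth fractions (the oracle)."""
    if panel is None:
        panel = list(truth_by_target)
    q = [truth_by_target[t][0] for t in panel]
    im = [truth_by_target[t][2] for t in panel]
    nm = [truth_by_target[t][3] for t in panel]
    return p_mut(q), p_fs(q, im, nm)


@dataclass
class SimulatedCohort:
    """A simulated cohort: pools per animal/amplicon plus exact truth."""

    config: SimulationConfig
    amplicons: dict[str, Amplicon]
    targets: list[SgRNATarget]
    #: animal_id -> amplicon_id -> pool
    pools: dict[str, dict[str, AllelePool]]
    #: per-animal read-generation seeds (decoupled from pool generation)
    _read_seeds: dict[str, int]

    @property
    def animal_ids(self) -> list[str]:
        return list(self.pools)

    def animal_reads(self, animal_id: str) -> dict[str, list[ReadRecord]]:
        """Deterministic reads for one animal, keyed by amplicon id."""
        rng = np.random.default_rng(self._read_seeds[animal_id])
        return {
            amp_id: simulate_reads(pool, self.config, rng)
            for amp_id, pool in sorted(self.pools[animal_id].items())
        }

    def truth_frame(self) -> pd.DataFrame:
        """Tidy truth table: one row per animal and scope.

        Columns: ``animal_id``, ``scope`` (target id or ``pooled``),
        ``theta``, ``q``, ``fs``, ``im``, ``nm``, ``p_mut``, ``p_fs``.
        """
        rows = []
        panel = [t.target_id for t in self.targets]
        for animal_id, by_amp in self.pools.items():
            truth_all: dict[str, tuple[float, float, float, float]] = {}
            theta_all: dict[str, float] = {}
            for pool in by_amp.values():
                truth_all.update(pool.truth)
                theta_all.update(pool.theta)
            for tid in panel:
                q, fs, im, nm = truth_all[tid]
                rows.append(
                    {
                        "animal_id": animal_id,
                        "scope": tid,
                        "theta": theta_all[tid],
                        "q": q,
                        "fs": fs,
                        "im": im,
                        "nm": nm,
                        "p_mut": p_mut([q]),
                        "p_fs": p_fs([q], [im], [nm]),
                    }
                )
            pm, pf = expected_lof(truth_all, panel)
            rows.append(
                {
                    "animal_id": animal_id,
                    "scope": POOLED_SCOPE,
                    "theta": float("nan"),
                    "q": float("nan"),
                    "fs": float("nan"),
                    "im": float("nan"),
                    "nm": float("nan"),
                    "p_mut": pm,
                    "p_fs": pf,
                }
            )
        return pd.DataFrame(rows)

    def allele_frame(self) -> pd.DataFrame:
        """One row per animal, amplicon and founder allele."""
        rows = []
        for animal_id, by_amp in self.pools.items():
            for amp_id, pool in by_amp.items():
                for al in pool.alleles:
                    desc = ";".join(
                        f"{tid}:{ev.kind[:3]}@{ev.ref_start}x{ev.length}"
                        + (f":{ev.alt}" if ev.alt else "")
                        for tid, ev in sorted(al.events.items())
                    )
                    rows.append(
                        {
                            "animal_id": animal_id,
                            "amplicon_id": amp_id,
                            "edit": desc or "WT",
                            "frequency": al.frequency,
                        }
                    )
        return pd.DataFrame(rows)


def simulate_cohort(
    config: SimulationConfig,
    targets: Sequence[SgRNATarget],
    amplicons: Mapping[str, Amplicon],
) -> SimulatedCohort:
    """Simulate a whole cohort deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    by_amp: dict[str, list[SgRNATarget]] = {}
    for t in targets:
        by_amp.setdefault(t.amplicon_id, []).append(t)

    pools: dict[str, dict[str, AllelePool]] = {}
    read_seeds: dict[str, int] = {}
    for i in range(config.n_animals):
        animal_id = f"animal{i + 1:03d}"
        pools[animal_id] = {}
        for amp_id in sorted(by_amp):
            pools[animal_id][amp_id] = simulate_allele_pool(
                config, by_amp[amp_id], amplicons[amp_id], rng, animal_id
            )
        read_seeds[animal_id] = int(rng.integers(0, 2**31 - 1))
    return SimulatedCohort(
        config=config,
        amplicons=dict(amplicons),
        targets=list(targets),
        pools=pools,
        _read_seeds=read_seeds,
    )


# ---------------------------------------------------------------------------
# demo panel + file output


def demo_panel(
    n_targets: int = 3,
    seed: int = 20180201,
    amplicon_length: int = 250,
    window_halfwidth: int = 5,
) -> tuple[dict[str, Amplicon], list[SgRNATarget]]:
    """A small synthetic sgRNA panel, one amplicon per target.

    Amplicon sequences are random with a planted NGG protospacer
    (alternating strands) and a coding interval covering the cut, mimicking
    a typical exon-targeting amplicon design.
    """
    rng = np.random.default_rng(seed)
    amplicons: dict[str, Amplicon] = {}
    targets: list[SgRNATarget] = []
    for i in range(n_targets):
        seq = list("ACGT"[j] for j in rng.integers(0, 4, amplicon_length))
        amp_id = f"amp{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            pam_start = 120
            seq[pam_start + 1] = "G"
            seq[pam_start + 2] = "G"
            amp = Amplicon(amp_id, "".join(seq), ((60, 200),))
            proto = amp.sequence[pam_start - 20 : pam_start]
        else:
            pam_start = 100
            seq[pam_start] = "C"
            seq[pam_start + 1] = "C"
            amp = Amplicon(amp_id, "".join(seq), ((60, 200),))
            from .amplicons import revcomp

            proto = revcomp(amp.sequence[pam_start + 3 : pam_start + 23])
        t = SgRNATarget(
            target_id=f"sgRNA{i + 1}",
            amplicon_id=amp_id,
            protospacer=proto,
            strand=strand,
            pam_start=pam_start,
            window_halfwidth=window_halfwidth,
        )
        validate_target(t, amp)
        amplicons[amp_id] = amp
        targets.append(t)
    return amplicons, targets


def write_panel(amplicons: Mapping[str, Amplicon], targets: Sequence[SgRNATarget], outdir) -> dict[str, str]:
    """Write FASTA/TSV/BED panel files; returns their paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "amplicons.fasta"
    with open(fasta, "w") as fh:
        for amp in amplicons.values():
            fh.write(f">{amp.amplicon_id}\n{amp.sequence}\n")
    bed = outdir / "coding.bed"
    with open(bed, "w") as fh:
        for amp in amplicons.values():
            for s, e in amp.coding_intervals:
                fh.write(f"{amp.amplicon_id}\t{s}\t{e}\n")
    tsv = outdir / "targets.tsv"
    pd.DataFrame(
        [
            {
                "target_id": t.target_id,
                "amplicon_id": t.amplicon_id,
                "protospacer": t.protospacer,
                "strand": t.strand,
                "pam_start": t.pam_start,
            }
            for t in targets
        ]
    ).to_csv(tsv, sep="\t", index=False)
    return {"fasta": str(fasta), "targets": str(tsv), "bed": str(bed)}


def write_fastq_gz(reads: Iterable[ReadRecord], path) -> None:
    """Write reads as gzipped FASTQ (constant Q40, mtime 0 for
    byte-identical output under a fixed seed)."""
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as gz:
            for read in reads:
                qual = "I" * len(read.sequence)
                gz.write(
                    f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n".encode("ascii")
                )
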