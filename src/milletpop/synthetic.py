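"""Synthetic two-population sequence panels with known ground truth.

The generator stands in for a multilocus Sanger resequencing survey of a
crop and its wild progenitor: nine unlinked loci of ~440-1014 aligned bp
(about 90% noncoding), wild sample sizes around 30 and cultivated around
45-50, per-site wild diversity near 0.006, and a
split-with-bottleneck-and-migration history relating the populations.

Haplotypes are simulated under the bottleneck coalescent and realized as
nucleotides on a random ancestral background: each infinite-sites variant
becomes a transition of the i.i.d.-uniform ancestral base, so every
downstream statistic computed from the FASTA equals the statistic of the
underlying binary matrix exactly.  An outgroup record carrying the
all-ancestral haplotype is emitted so that SFS polarization is exactly
testable.  Optionally, small 1-3 bp deletions can be injected to exercise
the gap-filtering path (off by default, in which case filtering is the
identity and the planted per-locus segregating-site counts round-trip).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coalescent import (CULT, WILD, DemographicModel, HaplotypeMatrix,
                         LocusSpec, simulate_bottleneck_panel)

__all__ = ["PanelSpec", "default_panel_loci", "generate_panel",
           "generate_summary_table", "realize_nucleotides"]

_TRANSITION = {b"A": b"G", b"G": b"A", b"C": b"T", b"T": b"C"}

# The nine-locus panel template: lengths (bp) and per-species sample sizes
# matching the published survey geometry.
_PANEL_TEMPLATE = [
    # locus,   L_wild, L_cult, n_wild, n_cult
    ("DACP", 1014, 964, 29, 46),
    ("SIGT", 732, 767, 29, 48),
    ("ADTY", 997, 1005, 31, 50),
    ("PP2C", 815, 760, 33, 47),
    ("SPS1", 716, 695, 31, 46),
    ("UPL", 656, 761, 32, 48),
    ("TIFIIF", 569, 624, 29, 44),
    ("TRAN", 440, 435, 32, 49),
    ("MDEH", 525, 549, 31, 43),
]


def default_panel_loci() -> list[LocusSpec]:
    return [LocusSpec(locus_id=name, L_wild=lw, L_cult=lc,
                      n_wild=nw, n_cult=nc)
            for name, lw, lc, nw, nc in _PANEL_TEMPLATE]


@dataclass
class PanelSpec:
    """Everything needed to generate a dataset bundle deterministically."""

    loci: list[LocusSpec] = field(default_factory=default_panel_loci)
    model: DemographicModel = field(
        default_factory=lambda: DemographicModel.from_theta(
            0.0059, rho_over_theta=1.0, t2=8000.0, d=1000.0, k=0.6,
            m12=1.0, m21=1.0))
    seed: int = 1
    coding_fraction: float = 0.10
    with_outgroup: bool = True
    indel_rate: float = 0.0  # fraction of samples receiving one 1-3 bp deletion

    def __post_init__(self):
        ids = [s.locus_id for s in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids must be unique")


def realize_nucleotides(hm: HaplotypeMatrix, L: int,
                        rng: np.random.Generator):
    """Map binary haplotypes onto nucleotide sequences of length L.

    Returns (matrix of bytes (n, L), ancestral sequence, integer column of
    each variant).  Fractional simulated positions are floored to integer
    columns; collisions shift right to the next free column (locus lengths
    far exceed segregating-site counts, so shifts are rare and tiny).
    """
    ancestral = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L)
    cols = []
    used = set()
    for p in np.floor(hm.positions).astype(int):
        c = min(int(p), L - 1)
        while c in used:
            c += 1
            if c >= L:  # wrap; only reachable in pathological tiny loci
                c = 0
                while c in used:
                    c += 1
        used.add(c)
        cols.append(c)
    cols = np.asarray(cols, dtype=int)
    matrix = np.tile(ancestral, (hm.genotypes.shape[0], 1))
    for j, c in enumerate(cols):
        derived = _TRANSITION[bytes(ancestral[c])]
        matrix[hm.genotypes[:, j] == 1, c] = derived
    return matrix, ancestral, cols


def _coding_interval(L: int, fraction: float) -> tuple[int, int]:
    """One in-frame coding interval of ~fraction*L bp, centred in the locus."""
    span = max(3, int(round(fraction * L / 3)) * 3)
    start = (L - span) // 2
    return start, start + span


def _inject_deletions(matrix: np.ndarray, rng: np.random.Generator,
                      rate: float) -> list[dict]:
    n, L = matrix.shape
    injected = []
    for i in range(n):
        if rng.random() < rate:
            size = int(rng.integers(1, 4))
            start = int(rng.integers(0, L - size))
            matrix[i, start:start + size] = b"-"
            injected.append({"row": i, "start": start, "size": size})
    return injected


def generate_panel(spec: PanelSpec, outdir: str | Path) -> dict:
    """Write a dataset bundle {loci/*.fasta, popmap.tsv, annotation.tsv,
    truth.json} and return the truth dictionary.

    Deterministic given (spec, spec.seed): regenerating with the same seed
    is byte-identical.
    """
    outdir = Path(outdir)
    (outdir / "loci").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    sim_seed = int(rng.integers(1, 2**31 - 1))
    panel = simulate_bottleneck_panel(spec.model, spec.loci, sim_seed)

    popmap_rows, annotation_rows = [], []
    truth = {
        "seed": spec.seed,
        "model": {
            "N_a": spec.model.N_a, "mu": spec.model.mu,
            "rho_over_theta": spec.model.rho_over_theta,
            "theta_site": spec.model.theta_site,
            "t2": spec.model.t2, "d": spec.model.d, "k": spec.model.k,
            "N_b": spec.model.N_b, "N_p": spec.model.N_p_effective,
            "m12": spec.model.m12, "m21": spec.model.m21,
        },
        "loci": {},
    }
    seen_samples = set()
    for locus, hm in zip(spec.loci, panel):
        L = int(locus.L_total)
        matrix, ancestral, cols = realize_nucleotides(hm, L, rng)
        names = ([f"w{i:03d}" for i in range(locus.n_wild)]
                 + [f"c{i:03d}" for i in range(locus.n_cult)])
        indels = _inject_deletions(matrix, rng, spec.indel_rate) \
            if spec.indel_rate else []
        records = [SeqRecord(Seq(row.tobytes().decode()), id=name,
                             description="")
                   for name, row in zip(names, matrix)]
        if spec.with_outgroup:
            records.append(SeqRecord(Seq(ancestral.tobytes().decode()),
                                     id="outgroup", description=""))
        SeqIO.write(records, str(outdir / "loci" / f"{locus.locus_id}.fasta"),
                    "fasta")
        for name, pop in zip(names, hm.pops):
            if name not in seen_samples:
                seen_samples.add(name)
                popmap_rows.append(
                    (name, "wild" if pop == WILD else "cultivated"))
        cstart, cend = _coding_interval(L, spec.coding_fraction)
        annotation_rows.append((locus.locus_id, cstart, cend, "coding", 0))
        G = hm.genotypes
        truth["loci"][locus.locus_id] = {
            "L": L,
            "coding": [cstart, cend],
            "S_total": int(G.shape[1]),
            "S_wild": int(((G[hm.pops == WILD] !=
                            G[hm.pops == WILD][0]).any(axis=0)).sum()),
            "S_cult": int(((G[hm.pops == CULT] !=
                            G[hm.pops == CULT][0]).any(axis=0)).sum()),
            "variant_columns": [int(c) for c in cols],
            "derived_counts": [int(x) for x in G.sum(axis=0)],
            "indels": indels,
        }
    if spec.with_outgroup and "outgroup" not in seen_samples:
        popmap_rows.append(("outgroup", "outgroup"))
    with open(outdir / "popmap.tsv", "w") as fh:
        fh.write("# sample_id\tpopulation\n")
        for name, pop in popmap_rows:
            fh.write(f"{name}\t{pop}\n")
    with open(outdir / "annotation.tsv", "w") as fh:
        fh.write("# locus\tstart\tend\tclass\tframe (0-based half-open)\n")
        for row in annotation_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth


def generate_summary_table(spec: PanelSpec, path: str | Path | None = None,
                         outdir: str | Path | None = None):
    """Run the statistics pipeline on a generated panel and emit a summary
    table in the observed-table schema, closing the loop for end-to-end
    ABC recovery tests.  Returns the DataFrame (and writes it when ``path``
    is given)."""
    import pandas as pd

    from .alignment_io import filter_sites, read_alignment, read_annotation, \
        read_popmap
    from .ld import rho_hat_per_locus
    from .popstats import summarize_locus
    from .tables import SUMMARY_COLUMNS, write_summary_table

    import tempfile

    if outdir is None:
        tmp = tempfile.TemporaryDirectory()
        outdir = tmp.name
    generate_panel(spec, outdir)
    outdir = Path(outdir)
    popmap = read_popmap(outdir / "popmap.tsv")
    rows = []
    for locus in spec.loci:
        aln = read_alignment(outdir / "loci" / f"{locus.locus_id}.fasta",
                             outdir / "annotation.tsv", popmap=popmap)
        # drop the outgroup before population statistics
        keep = [s for s in aln.sample_ids
                if aln.population_of[s] != "outgroup"]
        idx = [aln.sample_ids.index(s) for s in keep]
        aln.matrix = aln.matrix[idx]
        aln.sample_ids = keep
        fa = filter_sites(aln)
        for species in ("wild", "cultivated"):
            rho = rho_hat_per_locus(fa, species)
            s = summarize_locus(fa, species, rho_hat=rho)
            rows.append({
                "species": species, "locus": s.locus_id,
                "length": s.L_total, "silent": round(s.L_silent, 3),
                "n": s.n, "S": s.S,
                "pi": round(s.pi, 6), "pi_silent": round(s.pi_silent, 6),
                "theta_w": round(s.theta_w, 6),
                "theta_w_silent": round(s.theta_w_silent, 6),
                "tajima_D": round(s.tajima_D, 4) if np.isfinite(s.tajima_D)
                else np.nan,
                "fuli_Dstar": round(s.fuli_Dstar, 4)
                if np.isfinite(s.fuli_Dstar) else np.nan,
                "fuli_Fstar": round(s.fuli_Fstar, 4)
                if np.isfinite(s.fuli_Fstar) else np.nan,
                "rho": round(rho, 4) if np.isfinite(rho) else np.nan,
                "Rm": s.Rm, "Hap": s.Hap, "Hdiv": round(s.Hdiv, 3),
            })
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df = df.sort_values(["species", "locus"],
                        ascending=[False, True]).reset_index(drop=True)
    if path is not None:
        write_summary_table(df, path)
    return df
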