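"""Self-consistent synthetic pipeline inputs with planted symptom->gene signal.

The generator emulates, at reduced scale, the data shapes the pipeline
consumes in practice: a bibliographic co-mention corpus, a disease-gene
association table, an undirected PPI, and a benchmark of symptom-gene pairs.
The planted structure is:

* each symptom is linked to a few diseases (``diseases_per_symptom``);
* each disease owns a gene module — a block of genes that is internally
  connected in the PPI (stochastic-block-model edges at ``p_in`` within a
  module, ``p_out`` between, plus a spanning chain so every module is
  connected);
* every corpus record mentions one primary disease; with probability
  ``signal_strength`` it also mentions each symptom linked to that disease.
  Background mentions (``symptom_noise``, ``disease_noise`` per record) blur
  the signal the way incidental co-citation does;
* the ground truth maps each symptom to the genes of its linked diseases;
  the benchmark is the ground truth with a fraction ``benchmark_dropout``
  of genes removed, emulating benchmark incompleteness.

With ``signal_strength=0`` planted records never mention their symptom, so
symptom-disease similarity carries no information about the planted gene
modules and the pipeline should score at chance.  Identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cooccurrence import RecordCorpus, write_corpus
from .evaluation import BenchmarkSet
from .network import PhenoGenoNetwork

__all__ = ["SynthConfig", "SynthDataset", "generate", "write_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults define the standard study conditions."""

    n_symptoms: int = 20
    n_diseases: int = 60
    n_genes: int = 500
    n_records: int = 2000
    diseases_per_symptom: int = 3
    p_in: float = 0.30
    p_out: float = 0.01
    signal_strength: float = 0.9
    symptom_noise: float = 0.02
    disease_noise: float = 0.005
    benchmark_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "signal_strength", "symptom_noise",
                     "disease_noise", "benchmark_dropout"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_symptoms", "n_diseases", "n_genes", "n_records",
                     "diseases_per_symptom"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.diseases_per_symptom > self.n_diseases:
            raise ValueError("diseases_per_symptom exceeds n_diseases")
        if self.n_genes < self.n_diseases:
            raise ValueError(
                f"infeasible module sizes: {self.n_genes} genes cannot give each of "
                f"{self.n_diseases} diseases a nonempty module"
            )


@dataclass
class SynthDataset:
    """All pipeline inputs plus the planted ground truth."""

    corpus: RecordCorpus
    disease_genes: dict[str, set[str]]
    ppi_edges: list[tuple[str, str]]
    benchmark: dict[str, BenchmarkSet]
    ground_truth: dict[str, set[str]]
    config: SynthConfig

    def network(self) -> PhenoGenoNetwork:
        return PhenoGenoNetwork.from_edges(self.ppi_edges, self.disease_genes)


def _names(prefix: str, n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate(cfg: SynthConfig) -> SynthDataset:
    """Generate one self-consistent dataset from the config (deterministic in seed)."""
    rng = np.random.default_rng(cfg.seed)
    symptoms = _names("S", cfg.n_symptoms)
    diseases = _names("D", cfg.n_diseases)
    genes = _names("G", cfg.n_genes)

    # disease gene modules: contiguous equal blocks; leftover genes are background
    module_size = cfg.n_genes // cfg.n_diseases
    disease_genes = {
        d: set(genes[i * module_size : (i + 1) * module_size])
        for i, d in enumerate(diseases)
    }
    module_of = np.full(cfg.n_genes, -1)
    for i in range(cfg.n_diseases):
        module_of[i * module_size : (i + 1) * module_size] = i

    # symptom -> planted diseases, and the inverse map for record generation
    sym_diseases = {
        s: sorted(rng.choice(cfg.n_diseases, cfg.diseases_per_symptom, replace=False))
        for s in symptoms
    }
    dis_symptoms: dict[int, list[str]] = {i: [] for i in range(cfg.n_diseases)}
    for s, ds in sym_diseases.items():
        for d in ds:
            dis_symptoms[d].append(s)

    # PPI: stochastic block model + spanning chain inside each module
    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    same = (module_of[iu] == module_of[ju]) & (module_of[iu] >= 0)
    p = np.where(same, cfg.p_in, cfg.p_out)
    keep = rng.random(len(p)) < p
    edges = {(genes[a], genes[b]) for a, b in zip(iu[keep], ju[keep])}
    for i in range(cfg.n_diseases):
        block = genes[i * module_size : (i + 1) * module_size]
        edges.update(zip(block, block[1:]))
    ppi_edges = sorted(edges)

    # corpus: one primary disease per record + planted and background mentions
    noise_sym = rng.random((cfg.n_records, cfg.n_symptoms)) < cfg.symptom_noise
    noise_dis = rng.random((cfg.n_records, cfg.n_diseases)) < cfg.disease_noise
    primary = rng.integers(0, cfg.n_diseases, cfg.n_records)
    records = []
    for r in range(cfg.n_records):
        d = int(primary[r])
        rec_dis = {diseases[d]} | {diseases[j] for j in np.flatnonzero(noise_dis[r])}
        rec_sym = {symptoms[j] for j in np.flatnonzero(noise_sym[r])}
        for s in dis_symptoms[d]:
            if rng.random() < cfg.signal_strength:
                rec_sym.add(s)
        records.append((f"R{r:06d}", rec_sym, rec_dis))
    corpus = RecordCorpus.from_records(records, symptoms, diseases)

    ground_truth = {
        s: set().union(*(disease_genes[diseases[d]] for d in ds))
        for s, ds in sym_diseases.items()
    }
    benchmark = {}
    for s, gs in ground_truth.items():
        kept = sorted(gs)
        if cfg.benchmark_dropout > 0:
            n_drop = int(round(cfg.benchmark_dropout * len(kept)))
            n_drop = min(n_drop, len(kept) - 1)  # keep at least one gene
            drop = set(rng.choice(len(kept), n_drop, replace=False))
            kept = [g for i, g in enumerate(kept) if i not in drop]
        benchmark[s] = BenchmarkSet(s, frozenset(kept))

    return SynthDataset(corpus, disease_genes, ppi_edges, benchmark, ground_truth, cfg)


def write_dataset(ds: SynthDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the four pipeline input files plus the ground truth as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": outdir / "corpus.tsv",
        "disease_genes": outdir / "disease_genes.tsv",
        "ppi": outdir / "ppi.tsv",
        "benchmark": outdir / "benchmark.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_corpus(ds.corpus, paths["corpus"])
    with open(paths["disease_genes"], "w", encoding="utf-8") as fh:
        for d in sorted(ds.disease_genes):
            for g in sorted(ds.disease_genes[d]):
                fh.write(f"{d}\t{g}\n")
    with open(paths["ppi"], "w", encoding="utf-8") as fh:
        for a, b in ds.ppi_edges:
            fh.write(f"{a}\t{b}\t1\n")
    with open(paths["benchmark"], "w", encoding="utf-8") as fh:
        for s in sorted(ds.benchmark):
            for g in sorted(ds.benchmark[s].genes):
                fh.write(f"{s}\t{g}\n")
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        for s in sorted(ds.ground_truth):
            for g in sorted(ds.ground_truth[s]):
                fh.write(f"{s}\t{g}\n")
    return paths
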