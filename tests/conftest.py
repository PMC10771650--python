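"""Shared fixtures: a seeded synthetic study and a full pipeline run."""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from fiveutr.pipeline import RunConfig, run_pipeline
from fiveutr.sequence_effects import (
    ORF_EXTENSION,
    ORF_OORF,
    ORF_UORF,
    STOP_CODONS,
    UtrContext,
)
from fiveutr.synthetic_data import SimulationConfig, generate_all

SIM_SEED = 7


def make_run_config(d: Path, outdir: Path, **overrides) -> RunConfig:
    kw = dict(
        gtf=str(d / "annotation.gtf"),
        fasta=str(d / "genome.fa"),
        expression=str(d / "expression.tsv"),
        gene_list=str(d / "genes.txt"),
        vcf=str(d / "variants.vcf"),
        panel=str(d / "panel.tsv"),
        cases=str(d / "cases.tsv"),
        af_table=str(d / "af.tsv"),
        spliceai_table=str(d / "spliceai.tsv"),
        te_table=str(d / "te.tsv"),
        mfe_table=str(d / "mfe.tsv"),
        tss_bed=str(d / "tss.bed"),
        ires_bed=str(d / "ires.bed"),
        cohorts_table=str(d / "cohorts.tsv"),
        capture_beds=(str(d / "capture_broad.bed"), str(d / "capture_sparse.bed")),
        outdir=str(outdir),
    )
    kw.update(overrides)
    return RunConfig(**kw)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("sim")
    generate_all(SimulationConfig(seed=SIM_SEED), d)
    return d


@pytest.fixture(scope="session")
def truth(sim_dir) -> dict:
    return json.loads((sim_dir / "truth.json").read_text())


@pytest.fixture(scope="session")
def pipeline_result(sim_dir):
    config = make_run_config(sim_dir, sim_dir / "out")
    return run_pipeline(config)


@pytest.fixture(scope="session")
def annotation(sim_dir):
    from fiveutr.genome_model import load_annotation

    return load_annotation(sim_dir / "annotation.gtf", sim_dir / "genome.fa")


def brute_force_uorfs(ctx: UtrContext) -> list[tuple[int, str]]:
    """Independent uORF enumerator: (start offset, orf type) per uAUG.

    Naive re-derivation used as the oracle for the scanner: every ATG in
    the UTR, codon-by-codon stop search over the concatenated sequence,
    typing from first principles.
    """
    s = (ctx.utr_seq + ctx.cds_seq).upper()
    L = len(ctx.utr_seq)
    out = []
    for i in range(max(0, L - 2)):
        if s[i] != "A" or s[i + 1 : i + 3] != "TG":
            continue
        stop = None
        for j in range(i, len(s) - 2, 3):
            if s[j : j + 3] in STOP_CODONS:
                stop = j
                break
        if stop is not None and stop + 3 <= L:
            typ = ORF_UORF
        elif (L - i) % 3 == 0:
            typ = ORF_EXTENSION
        else:
            typ = ORF_OORF
        out.append((i, typ))
    return out
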