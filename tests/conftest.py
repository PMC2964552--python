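import numpy as np
import pytest

import milletpop as mp


@pytest.fixture(scope="session")
def observed():
    """The packaged observed per-locus summary table, per species."""
    return mp.load_observed_from_table()


@pytest.fixture(scope="session")
def small_panel_spec():
    """A small, fast synthetic panel: 3 loci, modest samples, known truth."""
    loci = [
        mp.LocusSpec("locA", 300, 300, 10, 14),
        mp.LocusSpec("locB", 450, 420, 10, 14),
        mp.LocusSpec("locC", 240, 260, 9, 12),
    ]
    model = mp.DemographicModel.from_theta(
        0.01, rho_over_theta=1.0, t2=8000, d=1000, k=0.6, m12=1.0, m21=1.0)
    return mp.PanelSpec(loci=loci, model=model, seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_panel_spec, tmp_path_factory):
    """Generated bundle directory + its truth dict."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = mp.generate_panel(small_panel_spec, outdir)
    return outdir, truth


def read_bundle_locus(outdir, locus_id, drop_outgroup=True):
    popmap = mp.read_popmap(outdir / "popmap.tsv")
    aln = mp.read_alignment(outdir / "loci" / f"{locus_id}.fasta",
                            outdir / "annotation.tsv", popmap=popmap)
    if drop_outgroup:
        keep = [s for s in aln.sample_ids
                if aln.population_of[s] != "outgroup"]
        idx = [aln.sample_ids.index(s) for s in keep]
        aln.matrix = aln.matrix[idx]
        aln.sample_ids = keep
    return aln


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
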