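import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import nucperiod as nc

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return nc.ChromatinModel()


@pytest.fixture(scope="session")
def small_chromatin(model):
    """A 300-core synthetic genome with fragments matching the true cores."""
    genome, cores, annotation = nc.generate_genome(model, n_arrays=300, seed=11)
    frags = nc.simulate_fragments(
        cores, jitter_sd=0.0, length_range=(147,), depth=1, seed=12,
        chrom_sizes=genome.lengths(),
    )
    classified = nc.classify_fragments(frags, annotation, flank=50)
    n147 = nc.select_n147(classified)
    return {
        "model": model,
        "genome": genome,
        "cores": cores,
        "annotation": annotation,
        "n147": n147,
    }


@pytest.fixture(scope="session")
def evolved_chromatin(small_chromatin):
    """Divergence and polymorphism simulated on the 300-core genome with
    in-phase focal modulation and in-phase positive selection."""
    from nucperiod.synthetic import alignment_to_site_table

    params = nc.EvolParams(
        beta=0.5, gamma=2.0, gamma_amplitude=2.0, theta=0.02, sample_size=34, seed=13
    )
    data = dict(small_chromatin)
    alignment = nc.simulate_divergence(data["genome"], data["cores"], params)
    data["params"] = params
    data["alignment"] = alignment
    data["sites"] = alignment_to_site_table(alignment, "chrS")
    data["polarized"] = nc.polarize(data["sites"])
    data["snps"] = nc.simulate_polymorphism(data["genome"], data["cores"], params)
    return data


def make_intervals(rng, n, chrom_len, min_len=50, max_len=200, chrom="c1"):
    starts = rng.integers(0, chrom_len - max_len, size=n)
    lengths = rng.integers(min_len, max_len, size=n)
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + lengths})
    df["length"] = df["end"] - df["start"]
    return df
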