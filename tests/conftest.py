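import hypothesis
import pandas as pd
import pytest

from n2oph import study_io, synthetic

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def default_config():
    return synthetic.SyntheticConfig(seed=20240101)


@pytest.fixture
def field_csv(tmp_path, default_config):
    """Default synthetic field-study dataset written to CSV, with truth."""
    obs, truth = synthetic.generate_field_dataset(default_config)
    path = tmp_path / "field.csv"
    study_io.field_observations_to_frame(obs).to_csv(path, index=False)
    return path, truth


@pytest.fixture
def gene_csv(tmp_path, default_config):
    obs, truth = synthetic.generate_gene_dataset(default_config)
    path = tmp_path / "genes.csv"
    study_io.gene_observations_to_frame(obs).to_csv(path, index=False)
    return path, truth


@pytest.fixture
def incubation_csv(tmp_path, default_config):
    """Zero-noise paired incubation bottles in long CSV format, with truth."""
    series, truth = synthetic.generate_incubation_pairs(default_config)
    ph = {f"I{i:04d}": p for i, p in enumerate(truth["ph"])}
    rows = []
    for s in series:
        stem = s.sample_id.rsplit("-", 1)[0]
        for t, c in zip(s.timepoints, s.headspace_ppm):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "acetylene": int(s.acetylene),
                    "soil_dry_mass": s.soil_dry_mass,
                    "bottle_volume": s.bottle_volume,
                    "temperature_c": s.temperature_c,
                    "ph_h2o": ph[stem],
                    "time_h": t,
                    "ppm": c,
                }
            )
    path = tmp_path / "incubation.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path, truth
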