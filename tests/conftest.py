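import numpy as np
import pytest

from peakcloud import simdata
from peakcloud.estimator import annotated_to_training_cloud
from peakcloud.extractor import PipelineConfig
from peakcloud.preprocess import Analyzer, ResolutionModel


@pytest.fixture(scope="session")
def sim_config():
    return simdata.SimConfig()


@pytest.fixture(scope="session")
def pipeline_config():
    # single window covering a whole simulated cloud
    return PipelineConfig(window_rt=10.0, window_mz=1.0,
                          expansion_rt=0.0, expansion_mz=0.0)


@pytest.fixture(scope="session")
def annotated_cloud(sim_config):
    cloud, truth = simdata.generate_cloud(sim_config, seed=42)
    return cloud, truth


@pytest.fixture(scope="session")
def normalized_cloud(annotated_cloud, pipeline_config):
    cloud, _ = annotated_cloud
    return annotated_to_training_cloud(cloud, pipeline_config)


@pytest.fixture(scope="session")
def tof_model():
    return ResolutionModel(Analyzer.TOF, 30000.0, 500.0)


@pytest.fixture(scope="session")
def orbitrap_model():
    return ResolutionModel(Analyzer.ORBITRAP, 140000.0, 200.0)
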