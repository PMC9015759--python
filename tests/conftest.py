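import io
import json

import pytest

from openexposures.pipeline import run_pipeline
from openexposures.synth import SimulationConfig, generate


@pytest.fixture(scope="session")
def small_bundle():
    """A modest simulated cohort with the published default effects."""
    return generate(SimulationConfig(seed=42, n_patients=4000, extra_null_features=2))


@pytest.fixture(scope="session")
def pipeline_result(small_bundle):
    return run_pipeline(small_bundle)


@pytest.fixture(scope="session")
def feature_table(pipeline_result):
    return pipeline_result.feature_table


@pytest.fixture()
def wsgi_call():
    """Invoke a WSGI app in-process: returns (status, headers, body_bytes)."""

    def call(app, method, path, body=None, accept="application/json"):
        raw = json.dumps(body).encode() if body is not None else b""
        environ = {
            "REQUEST_METHOD": method,
            "PATH_INFO": path,
            "CONTENT_LENGTH": str(len(raw)),
            "wsgi.input": io.BytesIO(raw),
            "HTTP_ACCEPT": accept,
        }
        captured = {}

        def start_response(status, headers):
            captured["status"] = status
            captured["headers"] = dict(headers)

        payload = b"".join(app(environ, start_response))
        return captured["status"], captured["headers"], payload

    return call
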