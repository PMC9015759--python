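"""HTTP facade: an open cohort-query service over local feature tables.

A small WSGI application (standard library only, servable with
``wsgiref``) reproducing the open-API interaction shape:

* ``POST /patient/{year}/cohort`` — define a cohort from a constraint set;
  returns a stable opaque ``COHORT:<hash>`` identifier and its size.
* ``GET /patient/{year}/cohort/{cohort_id}`` — echo a cohort definition.
* ``POST /patient/{year}/cohort/{cohort_id}/associations_to_all_features`` —
  run the chi-square battery of a dichotomized outcome against every other
  feature; body ``{"feature": {name: {"operator": op, "value": v}},
  "maximum_p_value": p}``. ``Accept: text/tabular`` yields the tabular
  projection, anything else JSON.
* ``GET /openapi.json`` — machine-readable interface description.

Responses only ever contain bin labels and aggregate counts; identifiers,
geocodes, dates, and raw exposure estimates never appear (they are absent
from the feature tables by construction).
"""

from __future__ import annotations

import json
import logging
from typing import Dict

from .errors import DegenerateTableError, ValidationError
from .stats import CohortDefinition, OutcomeFeature, associations_to_all_features, \
    define_cohort, results_to_frame
from .table import FeatureTable

logger = logging.getLogger(__name__)

__all__ = ["create_app", "serve", "ALL_COHORT_ID"]

ALL_COHORT_ID = "COHORT:all"

_OPENAPI = {
    "openapi": "3.0.0",
    "info": {"title": "openexposures cohort-query service", "version": "0.1.0"},
    "paths": {
        "/patient/{year}/cohort": {
            "post": {"summary": "Define a cohort from feature constraints",
                     "requestBody": {"content": {"application/json": {}}}}},
        "/patient/{year}/cohort/{cohort_id}": {
            "get": {"summary": "Retrieve a cohort definition and size"}},
        "/patient/{year}/cohort/{cohort_id}/associations_to_all_features": {
            "post": {"summary": "Chi-square battery of an outcome dichotomy "
                                "against all other features",
                     "requestBody": {"content": {"application/json": {
                         "example": {"feature": {"TotalEDInpatientVisits":
                                                 {"operator": "=", "value": 0}},
                                     "maximum_p_value": 1}}}}}},
    },
}


class _HttpError(Exception):
    def __init__(self, status: str, message: str):
        self.status = status
        self.message = message


def create_app(registry: Dict[int, FeatureTable]):
    """WSGI app over a ``{study_year: FeatureTable}`` registry.

    Every registered year gets a pre-defined whole-table cohort under the id
    ``COHORT:all``; further cohorts are created via the cohort endpoint and
    held in memory under their stable hash ids.
    """
    if not registry:
        raise ValidationError("registry must contain at least one feature table")
    cohorts: Dict[int, Dict[str, CohortDefinition]] = {
        year: {ALL_COHORT_ID: define_cohort(tbl, [])[0]}
        for year, tbl in registry.items()
    }

    def app(environ, start_response):
        try:
            status, headers, body = _dispatch(environ)
        except _HttpError as exc:
            status = exc.status
            body = json.dumps({"error": exc.message}).encode()
            headers = [("Content-Type", "application/json")]
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("unhandled error")
            status = "500 Internal Server Error"
            body = json.dumps({"error": str(exc)}).encode()
            headers = [("Content-Type", "application/json")]
        headers.append(("Content-Length", str(len(body))))
        start_response(status, headers)
        return [body]

    def _dispatch(environ):
        method = environ["REQUEST_METHOD"]
        path = [p for p in environ.get("PATH_INFO", "/").split("/") if p]
        if method == "GET" and path == ["openapi.json"]:
            return ("200 OK", [("Content-Type", "application/json")],
                    json.dumps(_OPENAPI).encode())
        if len(path) >= 3 and path[0] == "patient":
            year = _get_year(path[1])
            table = registry[year]
            if method == "POST" and path[2:] == ["cohort"]:
                return _define(year, table, _read_json(environ))
            if len(path) >= 4 and path[2] == "cohort":
                cohort_id = path[3]
                if cohort_id not in cohorts[year]:
                    raise _HttpError("404 Not Found", f"unknown cohort {cohort_id}")
                definition = cohorts[year][cohort_id]
                if method == "GET" and len(path) == 4:
                    _, size = define_cohort(table, definition.constraints)
                    return ("200 OK", [("Content-Type", "application/json")],
                            json.dumps({"cohort_id": cohort_id,
                                        "constraints": definition.constraints,
                                        "size": size}).encode())
                if method == "POST" and path[4:] == ["associations_to_all_features"]:
                    return _associations(environ, table, definition)
        raise _HttpError("404 Not Found", "no such route")

    def _get_year(raw):
        try:
            year = int(raw)
        except ValueError:
            raise _HttpError("400 Bad Request", f"invalid year {raw!r}") from None
        if year not in registry:
            raise _HttpError("404 Not Found", f"no table registered for year {year}")
        return year

    def _define(year, table, body):
        raw = body.get("feature", body.get("constraints", {}))
        constraints = [(name, spec.get("operator", "="), spec.get("value"))
                       for name, spec in raw.items()]
        try:
            definition, size = define_cohort(table, constraints)
        except ValidationError as exc:
            raise _HttpError("400 Bad Request", str(exc)) from None
        cohorts[year][definition.cohort_id] = definition
        return ("200 OK", [("Content-Type", "application/json")],
                json.dumps({"cohort_id": definition.cohort_id, "size": size}).encode())

    def _associations(environ, table, definition):
        body = _read_json(environ)
        feature_spec = body.get("feature")
        if not isinstance(feature_spec, dict) or len(feature_spec) != 1:
            raise _HttpError("400 Bad Request",
                             "body must contain exactly one outcome under 'feature'")
        (name, spec), = feature_spec.items()
        try:
            outcome = OutcomeFeature(name, spec.get("operator", "="),
                                     spec.get("value", 0))
            results, m, alpha_adjusted, skipped = associations_to_all_features(
                table, definition, outcome,
                maximum_p_value=float(body.get("maximum_p_value", 1.0)),
                alpha=float(body.get("alpha", 0.05)),
                correction=body.get("correction", "bonferroni"))
        except (ValidationError, KeyError, DegenerateTableError) as exc:
            raise _HttpError("400 Bad Request", str(exc)) from None
        accept = environ.get("HTTP_ACCEPT", "")
        if "text/tabular" in accept:
            frame = results_to_frame(results)
            text = frame.to_csv(sep="\t", index=False, lineterminator="\n")
            return ("200 OK", [("Content-Type", "text/tabular")], text.encode())
        payload = {
            "outcome": {"feature": outcome.name, "operator": outcome.operator,
                        "value": outcome.value},
            "n_features_tested": m,
            "alpha_adjusted": alpha_adjusted,
            "skipped": skipped,
            "associations": [r.to_record() for r in results],
        }
        return ("200 OK", [("Content-Type", "application/json")],
                json.dumps(payload).encode())

    def _read_json(environ):
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
            raw = environ["wsgi.input"].read(length) if length else b"{}"
            body = json.loads(raw.decode() or "{}")
        except (ValueError, KeyError) as exc:
            raise _HttpError("400 Bad Request", f"malformed JSON body: {exc}") from None
        if not isinstance(body, dict):
            raise _HttpError("400 Bad Request", "body must be a JSON object")
        return body

    return app


def serve(registry: Dict[int, FeatureTable], host: str = "127.0.0.1",
          port: int = 16340):  # pragma: no cover - manual entry point
    """Serve the registry with the standard-library WSGI server (blocking)."""
    from wsgiref.simple_server import make_server

    app = create_app(registry)
    with make_server(host, port, app) as httpd:
        logger.info("serving on http://%s:%d", host, port)
        httpd.serve_forever()
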