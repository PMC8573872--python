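"""Packaged controlled vocabularies.

The open-ended string fields of the event model (diagnosis concepts, provider
specialties, lab organisms) are validated against term lists shipped with the
package, so that phenotype rules and cohort inputs share a single source of
truth.  The small closed sets (lab kinds, specimens, note sections, ...) are
Python enums in :mod:`aimphenotype.events`.
"""
from __future__ import annotations

from importlib.resources import files

import yaml


def _load() -> dict:
    text = (files("aimphenotype") / "data" / "vocabularies.yaml").read_text()
    return yaml.safe_load(text)


_DATA = _load()

CONCEPTS: frozenset[str] = frozenset(_DATA["concepts"])
SPECIALTIES: frozenset[str] = frozenset(_DATA["specialties"])
ORGANISMS: frozenset[str] = frozenset(_DATA["organisms"])
PATHOGENIC_BACTERIA: frozenset[str] = frozenset(_DATA["pathogenic_bacteria"])
CONTAMINANTS: frozenset[str] = frozenset(_DATA["contaminants"])
STERILE_SPECIMENS: frozenset[str] = frozenset(_DATA["sterile_specimens"])
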