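{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "PGDB-lite",
  "description": "Exchange format for annotated genome databases: replicons carrying ordered genes, proteins with sequences and annotations, reactions, heteromultimeric complexes, and propagation history records. Canonical files sort all keys and record lists and omit empty optional fields. Validated structurally by orthoprop.pgdb_model (the reference implementation); this document is the format's normative description.",
  "type": "object",
  "required": ["format", "version", "id", "replicons", "genes", "proteins"],
  "properties": {
    "format": {"const": "pgdb-lite"},
    "version": {"const": 1},
    "id": {"type": "string"},
    "provenance": {"type": "object"},
    "replicons": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "topology", "gene_order"],
        "properties": {
          "id": {"type": "string"},
          "topology": {"enum": ["linear", "circular"]},
          "gene_order": {
            "type": "array",
            "items": {"type": "string"},
            "uniqueItems": true,
            "description": "gene ids ordered by start coordinate; the adjacency source of truth"
          }
        }
      }
    },
    "genes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "replicon", "start", "end", "strand"],
        "properties": {
          "id": {"type": "string"},
          "replicon": {"type": "string"},
          "start": {"type": "integer", "minimum": 1, "description": "1-based inclusive"},
          "end": {"type": "integer", "minimum": 1},
          "strand": {"enum": ["+", "-"]},
          "name": {"type": "string"},
          "synonyms": {"type": "array", "items": {"type": "string"}},
          "product": {"type": "string", "description": "protein id; absent for RNA genes"},
          "evidence": {"type": "array", "items": {"type": "string"}},
          "propagated_from": {"type": "string", "description": "source gene id recorded at propagation"}
        }
      }
    },
    "proteins": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "gene", "sequence"],
        "properties": {
          "id": {"type": "string"},
          "gene": {"type": "string"},
          "sequence": {"type": "string", "pattern": "^[ACDEFGHIKLMNPQRSTVWYX]+$"},
          "name": {"type": "string"},
          "synonyms": {"type": "array", "items": {"type": "string"}},
          "go_annotations": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["term", "evidence_code"],
              "properties": {
                "term": {"type": "string", "pattern": "^GO:[0-9]{7}$"},
                "evidence_code": {"type": "string"},
                "with_ref": {"type": "string", "description": "supporting object, e.g. the source ortholog for ISO"}
              }
            }
          },
          "reactions": {"type": "array", "items": {"type": "string"}},
          "evidence": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "complexes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "components"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "components": {
            "type": "object",
            "additionalProperties": {"type": "integer", "minimum": 1},
            "description": "component id -> stoichiometry; ids may be proteins, sub-complexes, or RNA gene ids"
          },
          "reactions": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "reactions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string"},
          "ec_number": {"type": "string"},
          "name": {"type": "string"}
        }
      }
    },
    "propagation_records": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["target_gene", "source_gene", "changed_fields", "prior_values"],
        "properties": {
          "target_gene": {"type": "string"},
          "source_gene": {"type": "string"},
          "changed_fields": {
            "type": "array",
            "items": {
              "enum": ["gene_name", "gene_synonyms", "product_name", "product_synonyms", "go_terms", "reactions", "complex_membership"]
            }
          },
          "prior_values": {"type": "object"},
          "timestamp": {"type": "string"}
        }
      }
    }
  }
}
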