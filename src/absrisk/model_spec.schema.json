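{
 "$defs": {
  "CovariateDoc": {
   "additionalProperties": false,
   "properties": {
    "name": {
     "title": "Name",
     "type": "string"
    },
    "kind": {
     "enum": [
      "numeric",
      "categorical"
     ],
     "title": "Kind",
     "type": "string"
    },
    "levels": {
     "anyOf": [
      {
       "items": {
        "type": "string"
       },
       "type": "array"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Levels"
    }
   },
   "required": [
    "name",
    "kind"
   ],
   "title": "CovariateDoc",
   "type": "object"
  },
  "RateTableDoc": {
   "additionalProperties": false,
   "description": "Inline rate table (parallel arrays) or a relative file reference.",
   "properties": {
    "age": {
     "anyOf": [
      {
       "items": {
        "type": "integer"
       },
       "type": "array"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Age"
    },
    "rate": {
     "anyOf": [
      {
       "items": {
        "type": "number"
       },
       "type": "array"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Rate"
    },
    "path": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Path"
    }
   },
   "title": "RateTableDoc",
   "type": "object"
  },
  "ReferenceDoc": {
   "additionalProperties": false,
   "description": "Inline reference rows (records) or a relative CSV reference.",
   "properties": {
    "records": {
     "anyOf": [
      {
       "items": {
        "additionalProperties": true,
        "type": "object"
       },
       "type": "array"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Records"
    },
    "path": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Path"
    }
   },
   "title": "ReferenceDoc",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "properties": {
  "schema_version": {
   "default": "1",
   "title": "Schema Version",
   "type": "string"
  },
  "formula": {
   "title": "Formula",
   "type": "string"
  },
  "beta": {
   "additionalProperties": {
    "type": "number"
   },
   "title": "Beta",
   "type": "object"
  },
  "covariates": {
   "items": {
    "$ref": "#/$defs/CovariateDoc"
   },
   "minItems": 1,
   "title": "Covariates",
   "type": "array"
  },
  "reference": {
   "$ref": "#/$defs/ReferenceDoc"
  },
  "incidence": {
   "$ref": "#/$defs/RateTableDoc"
  },
  "mortality": {
   "$ref": "#/$defs/RateTableDoc"
  }
 },
 "required": [
  "formula",
  "beta",
  "covariates",
  "reference",
  "incidence",
  "mortality"
 ],
 "title": "ModelSpecDoc",
 "type": "object"
}
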