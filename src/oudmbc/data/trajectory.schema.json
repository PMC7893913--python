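{
  "$defs": {
    "AdherenceReport": {
      "description": "Raw PAQ-OUD answers for one visit.",
      "properties": {
        "days_missed_past_week": {
          "maximum": 7,
          "minimum": 0,
          "title": "Days Missed Past Week",
          "type": "integer"
        },
        "reasons": {
          "default": [],
          "items": {
            "type": "string"
          },
          "title": "Reasons",
          "type": "array",
          "uniqueItems": true
        },
        "took_more_than_prescribed": {
          "default": false,
          "title": "Took More Than Prescribed",
          "type": "boolean"
        }
      },
      "required": [
        "days_missed_past_week"
      ],
      "title": "AdherenceReport",
      "type": "object"
    },
    "AppliedChange": {
      "description": "The clinician's (or simulator's) actual choice recorded after a visit.",
      "properties": {
        "entered_continuation": {
          "default": false,
          "title": "Entered Continuation",
          "type": "boolean"
        },
        "new_frequency": {
          "anyOf": [
            {
              "$ref": "#/$defs/Frequency"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "new_total_daily_dose_mg": {
          "anyOf": [
            {
              "exclusiveMinimum": 0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "New Total Daily Dose Mg"
        }
      },
      "title": "AppliedChange",
      "type": "object"
    },
    "ChecklistResponse": {
      "description": "One administration of the OUD Symptom Checklist.\n\n``items`` holds exactly 11 yes/no responses, one per DSM-5 OUD\ncriterion; ``opioid_use_past_2wk`` is the supplementary use item.",
      "properties": {
        "items": {
          "items": {
            "type": "boolean"
          },
          "title": "Items",
          "type": "array"
        },
        "opioid_use_past_2wk": {
          "title": "Opioid Use Past 2Wk",
          "type": "boolean"
        },
        "visit_week": {
          "minimum": 0,
          "title": "Visit Week",
          "type": "number"
        }
      },
      "required": [
        "items",
        "opioid_use_past_2wk",
        "visit_week"
      ],
      "title": "ChecklistResponse",
      "type": "object"
    },
    "Frequency": {
      "enum": [
        "once_daily",
        "twice_daily"
      ],
      "title": "Frequency",
      "type": "string"
    },
    "Prescription": {
      "description": "Current buprenorphine prescription (buprenorphine component only).",
      "properties": {
        "frequency": {
          "$ref": "#/$defs/Frequency",
          "default": "once_daily"
        },
        "total_daily_dose_mg": {
          "exclusiveMinimum": 0,
          "title": "Total Daily Dose Mg",
          "type": "number"
        }
      },
      "required": [
        "total_daily_dose_mg"
      ],
      "title": "Prescription",
      "type": "object"
    },
    "VisitRecord": {
      "description": "One follow-up visit: instruments completed plus the applied change.",
      "properties": {
        "adherence": {
          "$ref": "#/$defs/AdherenceReport"
        },
        "applied": {
          "anyOf": [
            {
              "$ref": "#/$defs/AppliedChange"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "checklist": {
          "$ref": "#/$defs/ChecklistResponse"
        }
      },
      "required": [
        "checklist",
        "adherence"
      ],
      "title": "VisitRecord",
      "type": "object"
    }
  },
  "description": "A whole treatment episode for one patient.",
  "properties": {
    "baseline": {
      "$ref": "#/$defs/ChecklistResponse"
    },
    "initial_prescription": {
      "$ref": "#/$defs/Prescription"
    },
    "latent_class": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Latent Class"
    },
    "patient_id": {
      "title": "Patient Id",
      "type": "string"
    },
    "schema_version": {
      "default": "1.0",
      "title": "Schema Version",
      "type": "string"
    },
    "visits": {
      "default": [],
      "items": {
        "$ref": "#/$defs/VisitRecord"
      },
      "title": "Visits",
      "type": "array"
    }
  },
  "required": [
    "patient_id",
    "initial_prescription",
    "baseline"
  ],
  "title": "Trajectory",
  "type": "object"
}
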