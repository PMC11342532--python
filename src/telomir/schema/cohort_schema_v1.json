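{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "telomir cohort CSV schema",
  "version": "1",
  "description": "Subject-level case-control cohort table: one row per participant; delimited text, UTF-8, '.' decimal separator. Genotype columns hold effect-allele dosage (0/1/2) or 'X/Y' allele strings.",
  "type": "object",
  "required": ["subject_id", "status", "ltl"],
  "properties": {
    "subject_id": {"type": "string", "description": "unique participant identifier"},
    "status": {"enum": [0, 1], "description": "1 = case (CSVD), 0 = control"},
    "age": {"type": "number", "description": "years"},
    "sex": {"enum": [0, 1], "description": "1 = male, 0 = female"},
    "height": {"type": "number", "description": "cm"},
    "weight": {"type": "number", "description": "kg"},
    "bmi": {"type": "number", "description": "kg/m^2"},
    "sbp": {"type": "number", "description": "systolic blood pressure, mmHg"},
    "dbp": {"type": "number", "description": "diastolic blood pressure, mmHg"},
    "hcy": {"type": "number", "description": "homocysteine, umol/L"},
    "tg": {"type": "number", "description": "triglycerides, mmol/L"},
    "tc": {"type": "number", "description": "total cholesterol, mmol/L"},
    "ldl_c": {"type": "number", "description": "LDL cholesterol, mmol/L"},
    "hdl_c": {"type": "number", "description": "HDL cholesterol, mmol/L"},
    "glu": {"type": "number", "description": "fasting glucose, mmol/L"},
    "smoking": {"enum": [0, 1]},
    "drinking": {"enum": [0, 1]},
    "movement": {"enum": [0, 1], "description": "regular physical activity"},
    "ltl": {"type": "number", "minimum": 0, "description": "relative leukocyte telomere length, T/S ratio"}
  },
  "patternProperties": {
    "^rs[0-9]+$": {"enum": [0, 1, 2], "description": "effect-allele dosage at one SNP"}
  }
}
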