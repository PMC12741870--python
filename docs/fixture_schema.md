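# Plan-check JSON dialect

The dialect served by the synthetic fixture and consumed by the client.
Vendor plan-check dialects are proprietary; this schema is defined by this
repository and mirrors the *content* a secondary dose-verification system
stores per check. Unknown fields are preserved by the parser in
`PlanCheckDocument.extras`.

## Routes (HTTP mode)

| Route | Method | Body / response |
|---|---|---|
| `/auth` | POST | `{"token": "<token>"}` → `200 {"ok": true}` or `401` |
| `/patients/{patient_id}/checks` | GET | `{"checks": [<summary>, ...]}` (empty array for unknown patients) |
| `/checks/{check_id}` | GET | full document, or `404 {"error_str": ...}` |

GET routes require `Authorization: Bearer <token>`.

File-backed mode uses the same dialect: `index.json`
(`{"token": ..., "patients": {patient_id: [check_id, ...]}}`) plus one
`checks/<check_id>.json` per document. Ground truth, when emitted, lives in
a separate `ground_truth.json` and never flows through the client path.

## Check document

```json
{
  "checkId_str":      "CHK000042",
  "patientId_str":    "PT0001",
  "planName_str":     "IM103/ADP1402",
  "checkType_str":    "pretreatment",        // or "logfile"
  "timestamp_str":    "2024-01-15T08:10:00", // ISO-8601, sortable
  "linkedCheckId_str": "CHK000041",          // logfile checks only: the
                                             // delivered plan's pretreatment check
  "prescription_cGy": 220.0,                 // per-fraction, highest target tier
  "site_str":         "pelvis",
  "doseUnit_str":     "gy",                  // "cgy" inputs converted on read
  "structures": [
    {"name_str": "Bladder", "volume_cm3": 153.0,
     "densityOverride_gcc": null, "centroid_cm": [1.2, -3.4, 0.5]}
  ],
  "beams": [
    {"isocenter_cm": [0.1, 0.2, 0.3], "nControlPoints_int": 96,
     "gantryAngles_deg": [179.0, 0.0, -179.0],
     "collimatorAngle_deg": 30.0, "mu_float": 312.5}
  ],
  "dvh": {
    "tpms":      {"Bladder": [[0.0, 98.6], [0.5, 98.2], ...]},
    "secondary": {"Bladder": [[0.0, 98.7], ...]}
  }
}
```

Conventions:

* `planName_str` follows the adaptive naming grammar
  `[Reference Plan ID]/[SCH|ADP][2-digit fraction][2-digit suffix]`;
  reference plans carry only the reference ID.
* `dvh` holds **truncated** cumulative point lists `[dose, volume%]`:
  sorted by increasing dose, strictly inside (0, 100) volume-% (the flat
  100 % head and 0 % tail are omitted), monotone non-increasing. The two
  sources (planning/on-couch system vs. secondary calculation) are distinct
  series end-to-end.
* Every structure named under `dvh` must appear in `structures`.
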