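{
  "annual_patients": 2000,
  "cohorts": {
    "fls": {
      "n_attendees": 103,
      "n_patients": 515,
      "n_refractures_by_category": {
        "hip": 20,
        "other": 20,
        "vertebral": 19,
        "wrist": 18
      },
      "name": "FLS"
    },
    "usual": {
      "n_attendees": 0,
      "n_patients": 416,
      "n_refractures_by_category": {
        "hip": 22,
        "other": 23,
        "vertebral": 22,
        "wrist": 21
      },
      "name": "UsualCare"
    }
  },
  "cost_reference_year": 2016,
  "horizon_years": 3,
  "medication": {
    "adherence": {
      "initial": 1.0,
      "year_end_fractions": [
        0.5,
        0.35,
        0.25
      ]
    },
    "formulary": [
      {
        "cost_3yr_full_adherence": 1416.0,
        "name": "weighted_average_2016",
        "prescription_weight": 1.0
      }
    ],
    "prescription_rate": 0.6666
  },
  "nonresponder_cost_per_patient": 1428.82,
  "price_index": {
    "index_name": "Total Health Price Index",
    "values": {
      "2012": 94.1,
      "2013": 96.0,
      "2014": 97.8,
      "2015": 99.1,
      "2016": 100.0
    }
  },
  "refracture_categories": {
    "hip": {
      "national_count": 19000,
      "national_total_cost": 697062161.4545479
    },
    "other": {
      "national_count": 77000,
      "national_total_cost": 1001000000.0
    },
    "vertebral": {
      "national_count": 27000,
      "national_total_cost": 286301912.7272717
    },
    "wrist": {
      "national_count": 47000,
      "national_total_cost": 188000000.0
    }
  },
  "schema_version": 1,
  "stages": {
    "clinic_exam_treatment": {
      "consumables": 0.0,
      "fee_items": [
        {
          "label": "MBS_110_initial_consult",
          "n_uses": 103,
          "unit_fee": 150.9
        },
        {
          "label": "MBS_116_followup_consult",
          "n_uses": 103,
          "unit_fee": 75.5
        },
        {
          "label": "MBS_12306_bone_densitometry",
          "n_uses": 103,
          "unit_fee": 102.4
        },
        {
          "label": "MBS_65070_full_blood_count",
          "n_uses": 103,
          "unit_fee": 16.95
        },
        {
          "label": "MBS_66512_biochem_panel",
          "n_uses": 103,
          "unit_fee": 17.7
        },
        {
          "label": "MBS_66833_parathyroid_hormone",
          "n_uses": 103,
          "unit_fee": 29.65
        },
        {
          "label": "MBS_66716_thyroid_function",
          "n_uses": 103,
          "unit_fee": 24.8
        },
        {
          "label": "MBS_66695_vitamin_d",
          "n_uses": 103,
          "unit_fee": 30.05
        }
      ],
      "labor_hours": 488.5547531888545,
      "overhead_rate": 0.275,
      "wage_rate": 47.5
    },
    "ed_record_assessment": {
      "consumables": 0.0,
      "fee_items": [],
      "labor_hours": 324.35327141382874,
      "overhead_rate": 0.275,
      "wage_rate": 47.5
    },
    "followup_calls": {
      "consumables": 927.0,
      "fee_items": [],
      "labor_hours": 180.4296388028896,
      "overhead_rate": 0.275,
      "wage_rate": 47.5
    },
    "patient_gp_contact": {
      "consumables": 2163.0,
      "fee_items": [],
      "labor_hours": 327.66117647058826,
      "overhead_rate": 0.275,
      "wage_rate": 47.5
    }
  }
}
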