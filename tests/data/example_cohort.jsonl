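{"type": "patient", "patient_id": "EX-001", "sex": "male", "birth_date": "1960-05-20"}
{"type": "measurement", "patient_id": "EX-001", "date": "2015-03-01", "parameter": "weight", "value": 81.5}
{"type": "diagnosis", "patient_id": "EX-001", "date": "2016-01-10", "system": "ICD-10", "code": "F10.1"}
{"type": "measurement", "patient_id": "EX-001", "date": "2016-02-11", "parameter": "ggt", "value": 34.0}
{"type": "measurement", "patient_id": "EX-001", "date": "2016-02-11", "parameter": "fasting_glucose", "value": 5.6}
{"type": "text", "patient_id": "EX-001", "date": "2017-06-02", "text": "Tupakoi noin askin päivässä."}
{"type": "patient", "patient_id": "EX-002", "sex": "female", "birth_date": "1971-11-03"}
{"type": "measurement", "patient_id": "EX-002", "date": "2018-09-14", "parameter": "bmi", "value": 24.2}
{"type": "text", "patient_id": "EX-002", "date": "2019-04-30", "text": "Ei käytä alkoholia."}
{"type": "text", "patient_id": "EX-002", "date": "2019-04-30", "text": "Ei tupakoi."}
{"type": "diagnosis", "patient_id": "EX-002", "date": "2020-02-02", "system": "ICPC-2", "code": "T90"}
{"type": "patient", "patient_id": "EX-003", "sex": "female", "birth_date": "1980-01-15"}
{"type": "diagnosis", "patient_id": "EX-003", "date": "2014-08-19", "system": "ICD-10", "code": "B18.2"}
{"type": "measurement", "patient_id": "EX-003", "date": "2020-07-07", "parameter": "whr", "value": 0.86, "source": "simulated"}
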