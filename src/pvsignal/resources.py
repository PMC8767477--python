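"""Small openly-written terminology fixtures.

MedDRA is licensed terminology and is not redistributed here. Real analyses
must supply user TSV files (PT -> SOC map, drug-name lexicon, symptom-phrase
lexicon, labelled-PT set). The dictionaries below are a hand-written fixture
vocabulary of ~100 preferred terms mapped to genuine system-organ-class
names, sufficient for simulation, tests and worked examples.
"""

from __future__ import annotations

# --- PT -> primary SOC fixture map -----------------------------------------

PT_TO_SOC: dict[str, str] = {
    # psychiatric
    "Drug dependence": "Psychiatric disorders",
    "Drug abuse": "Psychiatric disorders",
    "Insomnia": "Psychiatric disorders",
    "Anxiety": "Psychiatric disorders",
    "Depression": "Psychiatric disorders",
    "Confusional state": "Psychiatric disorders",
    "Euphoric mood": "Psychiatric disorders",
    "Hallucination": "Psychiatric disorders",
    "Agitation": "Psychiatric disorders",
    "Irritability": "Psychiatric disorders",
    "Nervousness": "Psychiatric disorders",
    "Restlessness": "Psychiatric disorders",
    "Nightmare": "Psychiatric disorders",
    "Suicidal ideation": "Psychiatric disorders",
    "Completed suicide": "Psychiatric disorders",
    # general / administration site
    "Drug ineffective": "General disorders and administration site conditions",
    "Drug withdrawal syndrome": "General disorders and administration site conditions",
    "Drug tolerance": "General disorders and administration site conditions",
    "Pain": "General disorders and administration site conditions",
    "Fatigue": "General disorders and administration site conditions",
    "Feeling abnormal": "General disorders and administration site conditions",
    "Asthenia": "General disorders and administration site conditions",
    "Malaise": "General disorders and administration site conditions",
    "Chills": "General disorders and administration site conditions",
    "Pyrexia": "General disorders and administration site conditions",
    "Chest pain": "General disorders and administration site conditions",
    "Oedema peripheral": "General disorders and administration site conditions",
    "Death": "General disorders and administration site conditions",
    # nervous system
    "Dizziness": "Nervous system disorders",
    "Headache": "Nervous system disorders",
    "Somnolence": "Nervous system disorders",
    "Seizure": "Nervous system disorders",
    "Tremor": "Nervous system disorders",
    "Paraesthesia": "Nervous system disorders",
    "Hypoaesthesia": "Nervous system disorders",
    "Syncope": "Nervous system disorders",
    "Memory impairment": "Nervous system disorders",
    "Loss of consciousness": "Nervous system disorders",
    "Serotonin syndrome": "Nervous system disorders",
    "Cerebellar infarction": "Nervous system disorders",
    "Toxic encephalopathy": "Nervous system disorders",
    "Quadriplegia": "Nervous system disorders",
    "Hemiplegia": "Nervous system disorders",
    "Paraplegia": "Nervous system disorders",
    "Paralysis": "Nervous system disorders",
    "Neurovascular conflict": "Nervous system disorders",
    # gastrointestinal
    "Nausea": "Gastrointestinal disorders",
    "Vomiting": "Gastrointestinal disorders",
    "Constipation": "Gastrointestinal disorders",
    "Diarrhoea": "Gastrointestinal disorders",
    "Abdominal pain upper": "Gastrointestinal disorders",
    "Dry mouth": "Gastrointestinal disorders",
    "Dyspepsia": "Gastrointestinal disorders",
    "Volvulus": "Gastrointestinal disorders",
    "Large intestine perforation": "Gastrointestinal disorders",
    "Splenic artery aneurysm": "Gastrointestinal disorders",
    # injury / poisoning
    "Overdose": "Injury, poisoning and procedural complications",
    "Toxicity to various agents": "Injury, poisoning and procedural complications",
    "Fall": "Injury, poisoning and procedural complications",
    "Medication error": "Injury, poisoning and procedural complications",
    # immune
    "Drug hypersensitivity": "Immune system disorders",
    "Anaphylactic reaction": "Immune system disorders",
    # skin
    "Pruritus": "Skin and subcutaneous tissue disorders",
    "Hyperhidrosis": "Skin and subcutaneous tissue disorders",
    "Rash": "Skin and subcutaneous tissue disorders",
    "Urticaria": "Skin and subcutaneous tissue disorders",
    "Hematidrosis": "Skin and subcutaneous tissue disorders",
    # cardiac
    "Palpitations": "Cardiac disorders",
    "Tachycardia": "Cardiac disorders",
    "Toxic cardiomyopathy": "Cardiac disorders",
    "Cardiorenal syndrome": "Cardiac disorders",
    "Kounis syndrome": "Cardiac disorders",
    # vascular
    "Hypertension": "Vascular disorders",
    "Hypotension": "Vascular disorders",
    "Flushing": "Vascular disorders",
    "Femoral artery aneurysm": "Vascular disorders",
    "Iliac artery occlusion": "Vascular disorders",
    # respiratory
    "Dyspnoea": "Respiratory, thoracic and mediastinal disorders",
    "Cough": "Respiratory, thoracic and mediastinal disorders",
    "Respiratory depression": "Respiratory, thoracic and mediastinal disorders",
    "Diffuse alveolar damage": "Respiratory, thoracic and mediastinal disorders",
    # musculoskeletal
    "Arthralgia": "Musculoskeletal and connective tissue disorders",
    "Myalgia": "Musculoskeletal and connective tissue disorders",
    "Muscle spasms": "Musculoskeletal and connective tissue disorders",
    "Back pain": "Musculoskeletal and connective tissue disorders",
    "Rhabdomyolysis": "Musculoskeletal and connective tissue disorders",
    "Ligament calcification": "Musculoskeletal and connective tissue disorders",
    # infections
    "Cardiac infection": "Infections and infestations",
    "Empyema": "Infections and infestations",
    "Endocarditis": "Infections and infestations",
    # investigations
    "Blood pressure increased": "Investigations",
    "Heart rate increased": "Investigations",
    "Weight decreased": "Investigations",
    "Hepatic enzyme increased": "Investigations",
    # eye / ear
    "Vision blurred": "Eye disorders",
    "Mydriasis": "Eye disorders",
    "Vertigo": "Ear and labyrinth disorders",
    "Tinnitus": "Ear and labyrinth disorders",
    # metabolism
    "Decreased appetite": "Metabolism and nutrition disorders",
    "Hypoglycaemia": "Metabolism and nutrition disorders",
    "Hyponatraemia": "Metabolism and nutrition disorders",
    # renal
    "Urinary retention": "Renal and urinary disorders",
}

# --- default per-draw background event weights ------------------------------
# Relative frequencies loosely shaped like a spontaneous-report PT profile:
# a few dominant terms and a long tail. Sum <= 1; the remainder is spread by
# normalisation inside the simulator's baseline layer.

DEFAULT_EVENT_VOCABULARY: dict[str, float] = {
    "Drug dependence": 0.070,
    "Drug ineffective": 0.065,
    "Nausea": 0.060,
    "Overdose": 0.045,
    "Drug withdrawal syndrome": 0.045,
    "Vomiting": 0.040,
    "Dizziness": 0.040,
    "Somnolence": 0.038,
    "Headache": 0.038,
    "Insomnia": 0.035,
    "Pain": 0.033,
    "Fatigue": 0.030,
    "Anxiety": 0.028,
    "Toxicity to various agents": 0.025,
    "Drug hypersensitivity": 0.025,
    "Pruritus": 0.022,
    "Constipation": 0.022,
    "Hyperhidrosis": 0.020,
    "Seizure": 0.020,
    "Depression": 0.018,
    "Confusional state": 0.018,
    "Fall": 0.016,
    "Tremor": 0.016,
    "Rash": 0.014,
    "Diarrhoea": 0.014,
    "Dry mouth": 0.012,
    "Tachycardia": 0.012,
    "Dyspnoea": 0.010,
    "Vision blurred": 0.008,
    "Decreased appetite": 0.008,
    "Hypoglycaemia": 0.006,
    "Serotonin syndrome": 0.005,
    "Respiratory depression": 0.005,
    "Rhabdomyolysis": 0.003,
    "Femoral artery aneurysm": 0.002,
    "Hypotension": 0.010,
    "Vertigo": 0.008,
    "Urticaria": 0.006,
    "Myalgia": 0.008,
    "Back pain": 0.010,
}

# --- symptom phrase -> PT fixture lexicon -----------------------------------
# Lowercased surface phrases as patients write them in drug reviews.

DEFAULT_PHRASE_LEXICON: dict[str, str] = {
    "nausea": "Nausea",
    "felt nauseous": "Nausea",
    "upset stomach": "Nausea",
    "vomiting": "Vomiting",
    "threw up": "Vomiting",
    "dizziness": "Dizziness",
    "dizzy spells": "Dizziness",
    "light headed": "Dizziness",
    "headache": "Headache",
    "migraine headache": "Headache",
    "drowsiness": "Somnolence",
    "could not stay awake": "Somnolence",
    "insomnia": "Insomnia",
    "sleepless nights": "Insomnia",
    "could not sleep": "Insomnia",
    "itching": "Pruritus",
    "itchy skin": "Pruritus",
    "constipation": "Constipation",
    "severe sweating": "Hyperhidrosis",
    "night sweats": "Hyperhidrosis",
    "did not work": "Drug ineffective",
    "no relief at all": "Drug ineffective",
    "withdrawal symptoms": "Drug withdrawal syndrome",
    "withdrawal was terrible": "Drug withdrawal syndrome",
    "habit forming": "Drug dependence",
    "could not stop taking it": "Drug dependence",
    "addicted to it": "Drug dependence",
    "seizure": "Seizure",
    "convulsions": "Seizure",
    "tremors": "Tremor",
    "shaking hands": "Tremor",
    "anxiety": "Anxiety",
    "panic attacks": "Anxiety",
    "depressed mood": "Depression",
    "felt depressed": "Depression",
    "exhausted all day": "Fatigue",
    "extreme fatigue": "Fatigue",
    "more pain than before": "Pain",
    "pain got worse": "Pain",
    "worsen pain": "Pain",
    "dry mouth": "Dry mouth",
    "racing heart": "Tachycardia",
    "heart was racing": "Tachycardia",
    "blurred vision": "Vision blurred",
    "loss of appetite": "Decreased appetite",
    "hives": "Urticaria",
    "skin rash": "Rash",
    "diarrhea": "Diarrhoea",
    "confusion": "Confusional state",
    "felt confused": "Confusional state",
    "hallucinations": "Hallucination",
    "euphoric": "Euphoric mood",
    "felt high": "Euphoric mood",
    "memory problems": "Memory impairment",
    "pins and needles": "Paraesthesia",
    "fainted": "Syncope",
    "vertigo": "Vertigo",
    "ringing in my ears": "Tinnitus",
}

# --- drug-name lexicon fixture ----------------------------------------------

TRAMADOL_SYNONYMS: dict[str, set[str]] = {
    "tramadol": {
        "tramadol",
        "tramadol hcl",
        "tramadol hydrochloride",
        "tramadol hcl-acetaminophen",
        "ultram",
        "ultram er",
        "ultracet",
        "conzip",
        "tramal",
        "zydol",
    }
}

DEFAULT_BACKGROUND_DRUGS: list[str] = [
    "oxycodone",
    "hydrocodone",
    "morphine",
    "codeine",
    "ibuprofen",
    "naproxen",
    "acetaminophen",
    "gabapentin",
    "duloxetine",
    "sertraline",
]
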