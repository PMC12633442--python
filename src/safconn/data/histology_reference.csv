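area_a,area_b,histology_status,provenance
8,9,present,"primate tract-tracing literature, consistently reported"
8,46,present,"primate tract-tracing literature, consistently reported"
8,9/46,present,"primate tract-tracing literature, consistently reported"
8,44,present,"primate tract-tracing literature, consistently reported"
8,45,present,"primate tract-tracing literature, consistently reported"
8,47,present,"primate tract-tracing literature, consistently reported"
8,10,present,"primate tract-tracing literature, consistently reported"
8,11,absent,no histological precedence
8,13,present,"primate tract-tracing literature, consistently reported"
8,14,present,"primate tract-tracing literature, consistently reported"
8,24,present,"primate tract-tracing literature, consistently reported"
8,25,absent,no histological precedence
8,32,present,"primate tract-tracing literature, consistently reported"
9,46,present,"primate tract-tracing literature, consistently reported"
9,9/46,present,"primate tract-tracing literature, consistently reported"
9,44,present,"primate tract-tracing literature, consistently reported"
9,45,present,"primate tract-tracing literature, consistently reported"
9,47,present,"primate tract-tracing literature, consistently reported"
9,10,present,"primate tract-tracing literature, consistently reported"
9,11,present,"primate tract-tracing literature, consistently reported"
9,13,present,"primate tract-tracing literature, consistently reported"
9,14,present,"primate tract-tracing literature, consistently reported"
9,24,present,"primate tract-tracing literature, consistently reported"
9,25,absent,no histological precedence
9,32,present,"primate tract-tracing literature, consistently reported"
46,9/46,present,"primate tract-tracing literature, consistently reported"
46,44,present,"primate tract-tracing literature, consistently reported"
46,45,present,"primate tract-tracing literature, consistently reported"
46,47,present,"primate tract-tracing literature, consistently reported"
46,10,present,"primate tract-tracing literature, consistently reported"
46,11,absent,no histological precedence
46,13,absent,no histological precedence
46,14,absent,no histological precedence
46,24,present,"primate tract-tracing literature, consistently reported"
46,25,absent,no histological precedence
46,32,absent,no histological precedence; inferred from plain false-positive status
9/46,44,present,"primate tract-tracing literature, consistently reported"
9/46,45,present,"primate tract-tracing literature, consistently reported"
9/46,47,present,"primate tract-tracing literature, consistently reported"
9/46,10,present,"primate tract-tracing literature, consistently reported"
9/46,11,present,"primate tract-tracing literature, consistently reported"
9/46,13,present,"primate tract-tracing literature, consistently reported"
9/46,14,present,"primate tract-tracing literature, consistently reported"
9/46,24,present,"primate tract-tracing literature, consistently reported"
9/46,25,absent,no histological precedence
9/46,32,present,"primate tract-tracing literature, consistently reported"
44,45,present,"primate tract-tracing literature, consistently reported"
44,47,present,"primate tract-tracing literature, consistently reported"
44,10,absent,no histological precedence
44,11,absent,no histological precedence
44,13,absent,no histological precedence
44,14,absent,no histological precedence
44,24,present,"primate tract-tracing literature, consistently reported"
44,25,absent,no histological precedence; inferred from plain false-positive status
44,32,present,"primate tract-tracing literature, consistently reported"
45,47,present,"primate tract-tracing literature, consistently reported"
45,10,present,"primate tract-tracing literature, consistently reported"
45,11,present,"primate tract-tracing literature, consistently reported"
45,13,present,"primate tract-tracing literature, consistently reported"
45,14,absent,no histological precedence
45,24,present,"primate tract-tracing literature, consistently reported"
45,25,absent,no histological precedence
45,32,present,"primate tract-tracing literature, consistently reported"
47,10,present,"primate tract-tracing literature, consistently reported"
47,11,present,"primate tract-tracing literature, consistently reported"
47,13,present,"primate tract-tracing literature, consistently reported"
47,14,present,"primate tract-tracing literature, consistently reported"
47,24,present,"primate tract-tracing literature, consistently reported"
47,25,absent,no histological precedence
47,32,present,"primate tract-tracing literature, consistently reported"
10,11,present,"primate tract-tracing literature, consistently reported"
10,13,present,"primate tract-tracing literature, consistently reported"
10,14,present,"primate tract-tracing literature, consistently reported"
10,24,present,"primate tract-tracing literature, consistently reported"
10,25,present,"primate tract-tracing literature, consistently reported"
10,32,present,"primate tract-tracing literature, consistently reported"
11,13,present,"primate tract-tracing literature, consistently reported"
11,14,present,"primate tract-tracing literature, consistently reported"
11,24,present,"primate tract-tracing literature, consistently reported"
11,25,absent,no histological precedence
11,32,present,"primate tract-tracing literature, consistently reported"
13,14,present,"primate tract-tracing literature, consistently reported"
13,24,present,"primate tract-tracing literature, consistently reported"
13,25,present,"primate tract-tracing literature, consistently reported"
13,32,absent,no histological precedence
14,24,present,"primate tract-tracing literature, consistently reported"
14,25,present,"primate tract-tracing literature, consistently reported"
14,32,present,"primate tract-tracing literature, consistently reported"
24,25,present,"primate tract-tracing literature, consistently reported"
24,32,present,"primate tract-tracing literature, consistently reported"
25,32,present,"primate tract-tracing literature, consistently reported"
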