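b1	Mental functions
b110	Consciousness functions
b152	Emotional functions
b164	Higher-level cognitive functions
b1641	Organization and planning
d2	General tasks and demands
d230	Carrying out daily routine
d5	Self-care
d530	Toileting
d5308	Toileting, other specified
d540	Dressing
d550	Eating
d6	Domestic life
d610	Acquiring a place to live
d7	Interpersonal interactions and relationships
d760	Family relationships
d8	Major life areas
d810	Informal education
d840	Apprenticeship (work preparation)
d850	Remunerative employment
d8502	Full-time employment
d859	Work and employment, other specified and unspecified
d865	Complex economic transactions
d870	Economic self-sufficiency
d8700	Personal economic resources
d9	Community, social and civic life
d920	Recreation and leisure
d9201	Sports
e3	Support and relationships
e340	Personal care providers and personal assistants
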