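# index	group	subject	states
1	Prostomium	Shape	Rectangular, sides parallel | Trapezoidal, wider posteriorly | Ovoid
2	Prostomium	Posterior margin	Well defined | Indistinct medially
3	Prostomium	Antennae number	Three | Two
4	Prostomium	Antennae shape	Cylindrical, tapered | Regularly constricted (moniliform)
5	Prostomium	Median antenna position	Anterior, over the anterior margin | Central | Posterior, towards the posterior margin
6	Prostomium	Palps	Present | Absent
7	Prostomium	Palp articulation	Biarticulate | Simple
8	Prostomium	Palps position	Ventro-terminal (bases not visible from above) | Distal, on the anterior prostomial margin | Ventral (palp bases not visible from above)
9	Prostomium	Eyes	Present | Absent
10	Prostomium	Number of eyes	Two pairs | One pair
11	Anterior segments and cirri	Relative fusion between successive tentacular segments	Segments indistinct with cirri anteriorly displaced, not regularly separated | Segments distinct with cirri regularly separated
12	Anterior segments and cirri	Pairs of cirri	Eight | Six | Four | Three | Two
13	Anterior segments and cirri	Size of cirri	Longer than body width | As long as body width | Shorter than body width
14	Anterior segments and cirri	Relative size of anterior cirri regarding dorsal cirri of chaetigers 1-2	Slightly longer or of about the same size | Markedly longer (at least twice as long) | Shorter
15	Anterior segments and cirri	Cirri base	Cylindrical | Subconical
16	Parapodia	Alignment	All neuropodia lateral | Few anterior neuropodia dorsal | First neuropodia ventral
17	Parapodia	Dorsal cirri shape	Tapered | Digitate | Subdistally swollen | state 3 (undocumented in source character list)
18	Parapodia	Dorsal cirrostyle margins	Articulated | Smooth
19	Parapodia	Dorsal cirrophore	Cylindrical | Subconical | Globose or scale-shaped
20	Parapodia	Dorsal cirri size	Three or more times longer than ventral cirri | Twice as long as ventral cirri | As long as ventral cirri, or shorter
21	Anterior parapodia chaetae	First chaetiger chaetae	Similar to chaetae in chaetiger 6 | Different from chaetiger 6
22	Anterior parapodia chaetae	Anterior neurohooks	Absent | Present
23	Anterior parapodia chaetae	Anterior neurohook blade	Compressed, as long as wide | Tapered, markedly longer than wide
24	Median parapodia notochaetae	Presence	Present | Absent
25	Median parapodia notochaetae	Number of notochaetae	1-4 | Five or more
26	Median parapodia notochaetae	Notochaetae capillaries	Present | Absent
27	Median parapodia notochaetae	Notochaetae spines	Absent | Present
28	Median parapodia notochaetae	Notochaetae hooks	Absent | Present
29	Median parapodia notochaetae	Modified notochaetae denticulates	Absent | Present
30	Median parapodia notochaetae	Modified notochaetae pectinates	Absent | Present
31	Median parapodia neurochaetae	Compound neurochaetae	Present | Absent
32	Median parapodia neurochaetae	Handle	Chambered | Solid
33	Median parapodia neurochaetae	Tips	Only bidentate | Only unidentate | Both uni- and bidentate
34	Median parapodia neurochaetae	Blades size in the same chaetiger	Heterogeneous, of markedly varying size | Homogeneous, single-sized or of about the same size
35	Median parapodia neurochaetae	Neurochaetae spines	Absent | Present
36	Median parapodia neurochaetae	Tips of spines	Only unidentate | Only bidentate | Both uni- and bidentate
37	Median parapodia neurochaetae	Denticulate neurochaetae	Absent | Present
38	Median parapodia neurochaetae	Size in the same chaetiger	Heterogeneous, of markedly variable size | Homogeneous, single-sized or of about the same size
39	Posterior end	Pygidium margin	Not projected into an anal membrane | Transformed into an anal membrane
40	Posterior end	Anal membrane lobes	Foliose | Lobate | Convoluted
41	Posterior end	Anal membrane continuity	Continuous | Medially notched | Laterally separated or bipartite
42	Posterior end	Anal membrane margin	Smooth | Crenulated or fimbriated
43	Posterior end	Anal cirri	Present | Absent
44	Posterior end	Shape of anal cirri	Tapered | Basally swollen | Medially or subdistally swollen
45	Posterior end	Size of anal cirri	Two to five times longer than pygidial width | As long as pygidium width | Smaller than pygidium width
46	Male copulatory organs	Presence	Absent | Present
47	Male copulatory organs	Position	On dorsal surface | On prostomium | Intersegmental
48	Habitat	Symbiotic life	Free-living | Living in association with other invertebrates
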