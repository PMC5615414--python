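# Reconstructed default human miRNA lexicon; accession column holds
# synthetic placeholder identifiers (MIMAT9xxxxxx), not real miRBase records.
canonical_id	accession	aliases
let-7	MIMAT9000001	
let-7a	MIMAT9000002	
let-7b	MIMAT9000003	
let-7c	MIMAT9000004	
let-7d	MIMAT9000005	
let-7e	MIMAT9000006	
let-7f	MIMAT9000007	
let-7g	MIMAT9000008	
let-7i	MIMAT9000009	
lin-4	MIMAT9000010	
miR-1	MIMAT9000011	
miR-100	MIMAT9000012	
miR-101	MIMAT9000013	
miR-103	MIMAT9000014	
miR-106a	MIMAT9000015	
miR-106b	MIMAT9000016	
miR-107	MIMAT9000017	
miR-10a	MIMAT9000018	
miR-10b	MIMAT9000019	
miR-122	MIMAT9000020	
miR-122a	MIMAT9000021	
miR-124	MIMAT9000022	
miR-125a	MIMAT9000023	
miR-125b	MIMAT9000024	
miR-126	MIMAT9000025	
miR-127	MIMAT9000026	
miR-128	MIMAT9000027	
miR-129	MIMAT9000028	
miR-130a	MIMAT9000029	
miR-130b	MIMAT9000030	
miR-132	MIMAT9000031	
miR-133a	MIMAT9000032	
miR-133b	MIMAT9000033	
miR-134	MIMAT9000034	
miR-135a	MIMAT9000035	
miR-135b	MIMAT9000036	
miR-136	MIMAT9000037	
miR-137	MIMAT9000038	
miR-138	MIMAT9000039	
miR-139	MIMAT9000040	
miR-140	MIMAT9000041	
miR-141	MIMAT9000042	
miR-142	MIMAT9000043	
miR-143	MIMAT9000044	
miR-144	MIMAT9000045	
miR-145	MIMAT9000046	
miR-146a	MIMAT9000047	
miR-146b	MIMAT9000048	
miR-148a	MIMAT9000049	
miR-148b	MIMAT9000050	
miR-15	MIMAT9000051	
miR-15/16	MIMAT9000052	
miR-150	MIMAT9000053	
miR-151	MIMAT9000054	
miR-152	MIMAT9000055	
miR-154	MIMAT9000056	
miR-155	MIMAT9000057	
miR-15a	MIMAT9000058	
miR-15b	MIMAT9000059	
miR-16	MIMAT9000060	
miR-17	MIMAT9000061	
miR-17-92	MIMAT9000062	
miR-181a	MIMAT9000063	
miR-181b	MIMAT9000064	
miR-182	MIMAT9000065	
miR-183	MIMAT9000066	
miR-185	MIMAT9000067	
miR-186	MIMAT9000068	
miR-188	MIMAT9000069	
miR-18a	MIMAT9000070	
miR-190	MIMAT9000071	
miR-191	MIMAT9000072	
miR-192	MIMAT9000073	
miR-193a	MIMAT9000074	
miR-193b	MIMAT9000075	
miR-194	MIMAT9000076	
miR-195	MIMAT9000077	
miR-196a	MIMAT9000078	
miR-196b	MIMAT9000079	
miR-197	MIMAT9000080	
miR-199a	MIMAT9000081	
miR-199a-1	MIMAT9000082	
miR-199a-2	MIMAT9000083	
miR-199b	MIMAT9000084	
miR-19a	MIMAT9000085	
miR-19b	MIMAT9000086	
miR-200a	MIMAT9000087	
miR-200b	MIMAT9000088	
miR-200c	MIMAT9000089	
miR-203	MIMAT9000090	
miR-204	MIMAT9000091	
miR-205	MIMAT9000092	
miR-206	MIMAT9000093	
miR-208a	MIMAT9000094	
miR-208b	MIMAT9000095	
miR-20a	MIMAT9000096	
miR-21	MIMAT9000097	
miR-210	MIMAT9000098	
miR-212	MIMAT9000099	
miR-214	MIMAT9000100	
miR-215	MIMAT9000101	
miR-216a	MIMAT9000102	
miR-217	MIMAT9000103	
miR-218	MIMAT9000104	
miR-219	MIMAT9000105	
miR-22	MIMAT9000106	
miR-221	MIMAT9000107	
miR-222	MIMAT9000108	
miR-223	MIMAT9000109	
miR-224	MIMAT9000110	
miR-23a	MIMAT9000111	
miR-23b	MIMAT9000112	
miR-24	MIMAT9000113	
miR-25	MIMAT9000114	
miR-26a	MIMAT9000115	
miR-26b	MIMAT9000116	
miR-27a	MIMAT9000117	
miR-27b	MIMAT9000118	
miR-28	MIMAT9000119	
miR-296	MIMAT9000120	
miR-29a	MIMAT9000121	
miR-29b	MIMAT9000122	
miR-29c	MIMAT9000123	
miR-301a	MIMAT9000124	
miR-302a	MIMAT9000125	
miR-30a	MIMAT9000126	
miR-30b	MIMAT9000127	
miR-30c	MIMAT9000128	
miR-30d	MIMAT9000129	
miR-30e	MIMAT9000130	
miR-31	MIMAT9000131	
miR-32	MIMAT9000132	
miR-320	MIMAT9000133	
miR-326	MIMAT9000134	
miR-33	MIMAT9000135	
miR-335	MIMAT9000136	
miR-33a	MIMAT9000137	
miR-33a/b	MIMAT9000138	
miR-33b	MIMAT9000139	
miR-340	MIMAT9000140	
miR-342	MIMAT9000141	
miR-345	MIMAT9000142	
miR-34a	MIMAT9000143	
miR-34b	MIMAT9000144	
miR-34c	MIMAT9000145	
miR-361	MIMAT9000146	
miR-370	MIMAT9000147	
miR-375	MIMAT9000148	
miR-378	MIMAT9000149	
miR-423	MIMAT9000150	
miR-424	MIMAT9000151	
miR-429	MIMAT9000152	
miR-451	MIMAT9000153	
miR-483	MIMAT9000154	
miR-486	MIMAT9000155	
miR-497	MIMAT9000156	
miR-499	MIMAT9000157	
miR-503	MIMAT9000158	
miR-520a	MIMAT9000159	
miR-7	MIMAT9000160	
miR-9	MIMAT9000161	
miR-92a	MIMAT9000162	
miR-93	MIMAT9000163	
miR-96	MIMAT9000164	
miR-98	MIMAT9000165	
miR-99a	MIMAT9000166	
miR-99b	MIMAT9000167	
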