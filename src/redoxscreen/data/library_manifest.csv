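# Redox compound library manifest: 84 library plate compounds (Enzo
# Screen-Well Redox library, placeholder ids) plus 20 named bioactive
# redox compounds (Sigma).
compound_id,common_name,other_name,source,catalog_no
enzo-001,Redox library compound 1,,enzo,BML-2835
enzo-002,Redox library compound 2,,enzo,BML-2835
enzo-003,Redox library compound 3,,enzo,BML-2835
enzo-004,Redox library compound 4,,enzo,BML-2835
enzo-005,Redox library compound 5,,enzo,BML-2835
enzo-006,Redox library compound 6,,enzo,BML-2835
enzo-007,Redox library compound 7,,enzo,BML-2835
enzo-008,Redox library compound 8,,enzo,BML-2835
enzo-009,Redox library compound 9,,enzo,BML-2835
enzo-010,Redox library compound 10,,enzo,BML-2835
enzo-011,Redox library compound 11,,enzo,BML-2835
enzo-012,Redox library compound 12,,enzo,BML-2835
enzo-013,Redox library compound 13,,enzo,BML-2835
enzo-014,Redox library compound 14,,enzo,BML-2835
enzo-015,Redox library compound 15,,enzo,BML-2835
enzo-016,Redox library compound 16,,enzo,BML-2835
enzo-017,Redox library compound 17,,enzo,BML-2835
enzo-018,Redox library compound 18,,enzo,BML-2835
enzo-019,Redox library compound 19,,enzo,BML-2835
enzo-020,Redox library compound 20,,enzo,BML-2835
enzo-021,Redox library compound 21,,enzo,BML-2835
enzo-022,Redox library compound 22,,enzo,BML-2835
enzo-023,Redox library compound 23,,enzo,BML-2835
enzo-024,Redox library compound 24,,enzo,BML-2835
enzo-025,Redox library compound 25,,enzo,BML-2835
enzo-026,Redox library compound 26,,enzo,BML-2835
enzo-027,Redox library compound 27,,enzo,BML-2835
enzo-028,Redox library compound 28,,enzo,BML-2835
enzo-029,Redox library compound 29,,enzo,BML-2835
enzo-030,Redox library compound 30,,enzo,BML-2835
enzo-031,Redox library compound 31,,enzo,BML-2835
enzo-032,Redox library compound 32,,enzo,BML-2835
enzo-033,Redox library compound 33,,enzo,BML-2835
enzo-034,Redox library compound 34,,enzo,BML-2835
enzo-035,Redox library compound 35,,enzo,BML-2835
enzo-036,Redox library compound 36,,enzo,BML-2835
enzo-037,Redox library compound 37,,enzo,BML-2835
enzo-038,Redox library compound 38,,enzo,BML-2835
enzo-039,Redox library compound 39,,enzo,BML-2835
enzo-040,Redox library compound 40,,enzo,BML-2835
enzo-041,Redox library compound 41,,enzo,BML-2835
enzo-042,Redox library compound 42,,enzo,BML-2835
enzo-043,Redox library compound 43,,enzo,BML-2835
enzo-044,Redox library compound 44,,enzo,BML-2835
enzo-045,Redox library compound 45,,enzo,BML-2835
enzo-046,Redox library compound 46,,enzo,BML-2835
enzo-047,Redox library compound 47,,enzo,BML-2835
enzo-048,Redox library compound 48,,enzo,BML-2835
enzo-049,Redox library compound 49,,enzo,BML-2835
enzo-050,Redox library compound 50,,enzo,BML-2835
enzo-051,Redox library compound 51,,enzo,BML-2835
enzo-052,Redox library compound 52,,enzo,BML-2835
enzo-053,Redox library compound 53,,enzo,BML-2835
enzo-054,Redox library compound 54,,enzo,BML-2835
enzo-055,Redox library compound 55,,enzo,BML-2835
enzo-056,Redox library compound 56,,enzo,BML-2835
enzo-057,Redox library compound 57,,enzo,BML-2835
enzo-058,Redox library compound 58,,enzo,BML-2835
enzo-059,Redox library compound 59,,enzo,BML-2835
enzo-060,Redox library compound 60,,enzo,BML-2835
enzo-061,Redox library compound 61,,enzo,BML-2835
enzo-062,Redox library compound 62,,enzo,BML-2835
enzo-063,Redox library compound 63,,enzo,BML-2835
enzo-064,Redox library compound 64,,enzo,BML-2835
enzo-065,Redox library compound 65,,enzo,BML-2835
enzo-066,Redox library compound 66,,enzo,BML-2835
enzo-067,Redox library compound 67,,enzo,BML-2835
enzo-068,Redox library compound 68,,enzo,BML-2835
enzo-069,Redox library compound 69,,enzo,BML-2835
enzo-070,Redox library compound 70,,enzo,BML-2835
enzo-071,Redox library compound 71,,enzo,BML-2835
enzo-072,Redox library compound 72,,enzo,BML-2835
enzo-073,Redox library compound 73,,enzo,BML-2835
enzo-074,Redox library compound 74,,enzo,BML-2835
enzo-075,Redox library compound 75,,enzo,BML-2835
enzo-076,Redox library compound 76,,enzo,BML-2835
enzo-077,Redox library compound 77,,enzo,BML-2835
enzo-078,Redox library compound 78,,enzo,BML-2835
enzo-079,Redox library compound 79,,enzo,BML-2835
enzo-080,Redox library compound 80,,enzo,BML-2835
enzo-081,Redox library compound 81,,enzo,BML-2835
enzo-082,Redox library compound 82,,enzo,BML-2835
enzo-083,Redox library compound 83,,enzo,BML-2835
enzo-084,Redox library compound 84,,enzo,BML-2835
sigma-afungin,Afungin,,sigma,S545791
sigma-balsalazide-disodium,Balsalazide disodium,,sigma,B5438
sigma-catechin-gallate,Catechin gallate,,sigma,C0692
sigma-chlorogenic-acid,Chlorogenic acid,,sigma,C3878
sigma-delphinidin-chloride,Delphinidin chloride,,sigma,43725
sigma-diosmin,Diosmin,,sigma,D3525
sigma-epicatechin,Epicatechin,,sigma,E1753
sigma-ellagic-acid,Ellagic acid,,sigma,E2250
sigma-epicatechin-from-green-tea,Epicatechin from green tea,,sigma,E4018
sigma-epigallocatechin,Epigallocatechin,,sigma,E4268
sigma-fucoxanthin-carotenoid,Fucoxanthin carotenoid,,sigma,F6932
sigma-gallic-acid,Gallic acid,,sigma,G7384
sigma-gallocatechin,Gallocatechin,,sigma,G6657
sigma-ginkgolide-b,Ginkgolide B,,sigma,G6910
sigma-hesperidin,Hesperidin,,sigma,H5254
sigma-kaempferol,Kaempferol,,sigma,K0133
sigma-luteolin,Luteolin,,sigma,L9283
sigma-neochlorogenic-acid,Neochlorogenic acid,,sigma,94419
sigma-p-coumaric-acid,p-Coumaric acid,,sigma,C9008
sigma-rutin-hydrate,Rutin hydrate,,sigma,R5143
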