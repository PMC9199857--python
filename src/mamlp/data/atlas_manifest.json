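[
 {
  "name": "AAL1v1",
  "family": "AAL",
  "roi_count": 90,
  "span": [
   0,
   180
  ]
 },
 {
  "name": "AAL2v1",
  "family": "AAL",
  "roi_count": 116,
  "span": [
   180,
   412
  ]
 },
 {
  "name": "AAL3v1",
  "family": "AAL",
  "roi_count": 170,
  "span": [
   412,
   752
  ]
 },
 {
  "name": "AICHA_reordered",
  "family": "AICHA",
  "roi_count": 384,
  "span": [
   752,
   1520
  ]
 },
 {
  "name": "rBN_Atlas_246_1mm",
  "family": "Brainnetome",
  "roi_count": 246,
  "span": [
   1520,
   2012
  ]
 },
 {
  "name": "Brodmann",
  "family": "Brodmann",
  "roi_count": 41,
  "span": [
   2012,
   2094
  ]
 },
 {
  "name": "Gordon",
  "family": "Gordon",
  "roi_count": 333,
  "span": [
   2094,
   2760
  ]
 },
 {
  "name": "Hammersmith_83",
  "family": "Hammersmith",
  "roi_count": 83,
  "span": [
   2760,
   2926
  ]
 },
 {
  "name": "Hammersmith_95",
  "family": "Hammersmith",
  "roi_count": 95,
  "span": [
   2926,
   3116
  ]
 },
 {
  "name": "HarvardOxford",
  "family": "HarvardOxford",
  "roi_count": 113,
  "span": [
   3116,
   3342
  ]
 },
 {
  "name": "Juelich-thr25",
  "family": "Juelich",
  "roi_count": 103,
  "span": [
   3342,
   3548
  ]
 },
 {
  "name": "Tian_Subcortex_S1",
  "family": "Tian_Subcortex",
  "roi_count": 62,
  "span": [
   3548,
   3672
  ]
 },
 {
  "name": "Tian_Subcortex_S2",
  "family": "Tian_Subcortex",
  "roi_count": 54,
  "span": [
   3672,
   3780
  ]
 },
 {
  "name": "Tian_Subcortex_S3",
  "family": "Tian_Subcortex",
  "roi_count": 34,
  "span": [
   3780,
   3848
  ]
 },
 {
  "name": "Tian_Subcortex_S4_7T",
  "family": "Tian_Subcortex",
  "roi_count": 16,
  "span": [
   3848,
   3880
  ]
 },
 {
  "name": "MIST_36",
  "family": "MIST",
  "roi_count": 36,
  "span": [
   3880,
   3952
  ]
 },
 {
  "name": "MIST_64",
  "family": "MIST",
  "roi_count": 64,
  "span": [
   3952,
   4080
  ]
 },
 {
  "name": "MIST_122",
  "family": "MIST",
  "roi_count": 122,
  "span": [
   4080,
   4324
  ]
 },
 {
  "name": "MIST_197",
  "family": "MIST",
  "roi_count": 197,
  "span": [
   4324,
   4718
  ]
 },
 {
  "name": "MIST_325",
  "family": "MIST",
  "roi_count": 325,
  "span": [
   4718,
   5368
  ]
 },
 {
  "name": "MIST_444",
  "family": "MIST",
  "roi_count": 444,
  "span": [
   5368,
   6256
  ]
 },
 {
  "name": "Schaefer2018_100",
  "family": "Schaefer2018",
  "roi_count": 100,
  "span": [
   6256,
   6456
  ]
 },
 {
  "name": "Schaefer2018_200",
  "family": "Schaefer2018",
  "roi_count": 200,
  "span": [
   6456,
   6856
  ]
 },
 {
  "name": "Schaefer2018_400",
  "family": "Schaefer2018",
  "roi_count": 400,
  "span": [
   6856,
   7656
  ]
 },
 {
  "name": "Schaefer2018_600",
  "family": "Schaefer2018",
  "roi_count": 600,
  "span": [
   7656,
   8856
  ]
 },
 {
  "name": "Schaefer2018_800",
  "family": "Schaefer2018",
  "roi_count": 800,
  "span": [
   8856,
   10456
  ]
 },
 {
  "name": "Schaefer2018_1000",
  "family": "Schaefer2018",
  "roi_count": 1000,
  "span": [
   10456,
   12456
  ]
 },
 {
  "name": "Cerebellum-MNIflirt",
  "family": "SUIT",
  "roi_count": 28,
  "span": [
   12456,
   12512
  ]
 },
 {
  "name": "Yeo2011_7",
  "family": "Yeo",
  "roi_count": 7,
  "span": [
   12512,
   12526
  ]
 },
 {
  "name": "Yeo2011_17",
  "family": "Yeo",
  "roi_count": 17,
  "span": [
   12526,
   12560
  ]
 }
]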