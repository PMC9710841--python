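feature,extra,agree,consc,stabl,open,average
Efficiency-Ego,100.00,71.51,100.00,85.03,100.00,91.31
Reach Efficiency-Ego,56.04,60.21,95.65,100.00,63.19,75.02
Constraint-Ego,80.30,70.00,79.67,67.61,22.17,63.95
Closeness Centrality,71.78,93.77,64.25,54.41,33.48,63.54
Effective Size-Ego,47.72,100.00,29.50,62.61,43.91,56.75
Betweenness Centrality-Ego,54.69,60.23,46.94,44.11,22.25,45.65
Betweenness Centrality,57.14,25.50,47.60,61.80,33.87,45.18
Community Percent Size,37.78,23.65,59.92,50.67,46.35,43.67
Transitivity-Ego,36.44,32.43,48.48,48.55,33.35,39.85
Density-Ego,32.81,48.71,48.47,18.71,48.35,39.41
Average Similarity-Ego,26.16,64.69,32.35,42.60,13.08,35.78
Size-Ego,58.47,30.26,23.74,15.98,1.50,25.99
Centralization-Ego,24.76,40.75,26.60,21.33,11.66,25.02
Average Dyadic Redundancy-Ego,15.93,37.16,21.84,20.76,17.37,22.61
Degree Centrality,32.83,33.08,22.27,12.19,12.64,22.60
Week,11.94,20.34,10.93,17.09,0.24,12.11
Size,18.25,9.84,8.86,6.23,7.32,10.10
Centralization,7.41,9.39,9.32,6.83,8.52,8.29
Geodesic Distance-Ego,13.51,3.37,4.31,0.47,9.81,6.29
Transitivity,9.95,0.00,6.90,0.45,0.00,3.46
Density,5.92,3.61,4.07,2.01,0.00,3.12
Geodesic Distance,0.44,3.36,0.74,2.50,3.94,2.20
Number Ordered Pairs-Ego,6.62,3.66,0.00,0.00,0.00,2.06
Diameter,4.43,0.00,2.99,2.30,0.00,1.94
Number of Nodes,7.05,0.00,1.27,0.38,0.00,1.74
Number of Ordered Pairs,1.21,0.00,2.54,0.51,0.00,0.85
Number of Subcommunities,0.00,0.00,0.00,0.14,0.00,0.03
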