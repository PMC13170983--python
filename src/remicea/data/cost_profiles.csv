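arm,year,statistic,primary_care,other,secondary_care,hospital,medicines
control,1,mean,334.66,34.4,271.33,539.52,234.58
control,1,sd,258.03,116.51,418.33,2452.1,518.41
control,2,mean,370.52,38.09,300.4,597.33,259.71
control,2,sd,285.68,128.99,463.15,2714.82,573.95
control,3,mean,406.37,41.78,329.47,655.13,284.84
control,3,sd,313.32,141.47,507.97,2977.54,629.5
control,4,mean,442.23,45.46,358.54,712.94,309.98
control,4,sd,340.97,153.95,552.79,3240.27,685.05
control,5,mean,490.04,50.38,397.3,790.02,343.49
control,5,sd,377.83,170.6,612.55,3590.57,759.1
intervention,1,mean,299.16,41.9,241.34,345.25,186.03
intervention,1,sd,246.37,136.59,408.1,1501.68,430.73
intervention,2,mean,323.42,45.3,260.91,373.25,201.12
intervention,2,sd,266.35,147.67,441.19,1623.44,465.65
intervention,3,mean,342.29,47.94,276.13,395.02,212.85
intervention,3,sd,281.88,156.28,466.93,1718.15,492.82
intervention,4,mean,358.46,50.2,289.17,413.68,222.91
intervention,4,sd,295.2,163.66,488.99,1799.31,516.1
intervention,5,mean,377.32,52.85,304.4,435.46,234.64
intervention,5,sd,310.74,172.28,514.72,1894.02,543.26
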