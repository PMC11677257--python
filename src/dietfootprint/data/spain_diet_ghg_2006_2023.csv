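year,group,gco2e_per_day
2006,alcohol,43.4
2006,dairy,545.1
2006,eggs,58.6
2006,fats,295.1
2006,fish,585.3
2006,fruits,48.2
2006,global,3978.1
2006,grains,119.7
2006,legumes,7.8
2006,potatoes,11.6
2006,poultry,189.1
2006,red_meat,1989.9
2006,sugar,10.3
2006,vegetables,74.0
2007,alcohol,47.0
2007,dairy,564.3
2007,eggs,62.2
2007,fats,309.0
2007,fish,581.0
2007,fruits,50.9
2007,global,4040.1
2007,grains,126.2
2007,legumes,8.3
2007,potatoes,8.9
2007,poultry,214.9
2007,red_meat,1979.4
2007,sugar,11.2
2007,vegetables,76.8
2008,alcohol,45.9
2008,dairy,563.9
2008,eggs,63.1
2008,fats,310.5
2008,fish,549.0
2008,fruits,49.5
2008,global,4106.4
2008,grains,125.0
2008,legumes,8.2
2008,potatoes,12.6
2008,poultry,213.3
2008,red_meat,2077.3
2008,sugar,11.0
2008,vegetables,77.2
2009,alcohol,47.5
2009,dairy,571.5
2009,eggs,64.5
2009,fats,308.9
2009,fish,541.0
2009,fruits,49.6
2009,global,3928.7
2009,grains,126.3
2009,legumes,8.2
2009,potatoes,13.1
2009,poultry,214.9
2009,red_meat,1893.9
2009,sugar,11.6
2009,vegetables,77.7
2010,alcohol,46.1
2010,dairy,554.8
2010,eggs,63.6
2010,fats,291.9
2010,fish,525.6
2010,fruits,52.7
2010,global,3835.4
2010,grains,122.6
2010,legumes,8.4
2010,potatoes,12.6
2010,poultry,216.5
2010,red_meat,1850.5
2010,sugar,10.8
2010,vegetables,79.3
2011,alcohol,45.6
2011,dairy,558.8
2011,eggs,64.7
2011,fats,289.6
2011,fish,508.1
2011,fruits,50.8
2011,global,3731.4
2011,grains,122.0
2011,legumes,8.1
2011,potatoes,11.5
2011,poultry,214.9
2011,red_meat,1766.7
2011,sugar,10.5
2011,vegetables,79.9
2012,alcohol,44.9
2012,dairy,555.3
2012,eggs,68.4
2012,fats,285.8
2012,fish,498.5
2012,fruits,50.4
2012,global,3735.7
2012,grains,119.3
2012,legumes,8.2
2012,potatoes,11.9
2012,poultry,229.5
2012,red_meat,1775.3
2012,sugar,10.8
2012,vegetables,77.4
2013,alcohol,45.6
2013,dairy,553.5
2013,eggs,67.7
2013,fats,263.9
2013,fish,484.3
2013,fruits,49.6
2013,global,3663.3
2013,grains,118.9
2013,legumes,7.9
2013,potatoes,12.1
2013,poultry,227.9
2013,red_meat,1740.8
2013,sugar,10.5
2013,vegetables,80.6
2014,alcohol,44.3
2014,dairy,540.3
2014,eggs,66.6
2014,fats,266.2
2014,fish,465.7
2014,fruits,49.0
2014,global,3617.4
2014,grains,117.4
2014,legumes,7.8
2014,potatoes,12.1
2014,poultry,223.0
2014,red_meat,1737.0
2014,sugar,9.9
2014,vegetables,78.1
2015,alcohol,45.3
2015,dairy,543.8
2015,eggs,67.2
2015,fats,256.0
2015,fish,461.9
2015,fruits,51.8
2015,global,3564.7
2015,grains,114.9
2015,legumes,8.2
2015,potatoes,12.4
2015,poultry,221.4
2015,red_meat,1694.5
2015,sugar,9.4
2015,vegetables,78.0
2016,alcohol,47.0
2016,dairy,495.8
2016,eggs,63.3
2016,fats,243.7
2016,fish,448.2
2016,fruits,52.1
2016,global,3289.4
2016,grains,131.4
2016,legumes,6.9
2016,potatoes,10.1
2016,poultry,226.2
2016,red_meat,1479.1
2016,sugar,8.5
2016,vegetables,77.1
2017,alcohol,46.7
2017,dairy,496.3
2017,eggs,63.4
2017,fats,232.8
2017,fish,410.2
2017,fruits,52.8
2017,global,3182.8
2017,grains,127.5
2017,legumes,6.9
2017,potatoes,10.3
2017,poultry,216.5
2017,red_meat,1436.6
2017,sugar,8.3
2017,vegetables,74.5
2018,alcohol,40.8
2018,dairy,478.9
2018,eggs,69.9
2018,fats,245.4
2018,fish,404.4
2018,fruits,53.4
2018,global,3203.2
2018,grains,125.5
2018,legumes,6.6
2018,potatoes,9.3
2018,poultry,218.2
2018,red_meat,1470.8
2018,sugar,7.8
2018,vegetables,72.3
2019,alcohol,44.5
2019,dairy,480.9
2019,eggs,62.4
2019,fats,229.9
2019,fish,403.8
2019,fruits,51.9
2019,global,3160.2
2019,grains,126.6
2019,legumes,6.7
2019,potatoes,9.1
2019,poultry,216.5
2019,red_meat,1450.0
2019,sugar,7.4
2019,vegetables,70.4
2020,alcohol,48.5
2020,dairy,505.8
2020,eggs,66.4
2020,fats,229.8
2020,fish,426.2
2020,fruits,51.2
2020,global,3229.2
2020,grains,122.9
2020,legumes,7.4
2020,potatoes,9.5
2020,poultry,221.4
2020,red_meat,1456.6
2020,sugar,7.8
2020,vegetables,75.7
2021,alcohol,45.7
2021,dairy,530.3
2021,eggs,69.8
2021,fats,241.5
2021,fish,450.6
2021,fruits,55.2
2021,global,3333.1
2021,grains,125.6
2021,legumes,7.5
2021,potatoes,9.1
2021,poultry,227.9
2021,red_meat,1487.6
2021,sugar,7.2
2021,vegetables,75.2
2022,alcohol,42.9
2022,dairy,541.8
2022,eggs,69.4
2022,fats,246.2
2022,fish,414.5
2022,fruits,49.7
2022,global,3252.8
2022,grains,129.1
2022,legumes,7.4
2022,potatoes,9.0
2022,poultry,231.1
2022,red_meat,1433.0
2022,sugar,6.7
2022,vegetables,72.1
2023,alcohol,39.9
2023,dairy,552.9
2023,eggs,74.6
2023,fats,230.0
2023,fish,401.2
2023,fruits,50.1
2023,global,3281.4
2023,grains,127.5
2023,legumes,7.7
2023,potatoes,9.5
2023,poultry,245.6
2023,red_meat,1465.2
2023,sugar,7.4
2023,vegetables,69.8
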